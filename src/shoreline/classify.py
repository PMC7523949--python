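"""Methylation + APOE risk classification: logistic models, ROC/AUC, DeLong.

The classification layer combines continuous shore methylation with the APOE
epsilon-4 genotype in a multiple logistic regression and judges discrimination
by the area under the ROC curve.  The surface follows the statsmodels shape:
:class:`MethylationRiskModel` is built from a cohort DataFrame and ``fit()``
returns a :class:`MethylationRiskResults` carrying coefficients, standard
errors, AIC, a ``summary()`` table, and ROC evaluation — including transfer
of a fitted model to an independent cohort.

AUC here is the tie-adjusted concordance probability
``(#concordant + 1/2 #tied) / (n_pos * n_neg)`` (midrank convention), its
variance and the paired-curve comparison follow DeLong's structural
components, and the 95% CI is the DeLong-variance Wald interval truncated to
[0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "FeatureSpec",
    "RocResult",
    "SeparationError",
    "MethylationRiskModel",
    "MethylationRiskResults",
    "fit_logistic",
    "stepwise_select",
    "roc_auc",
    "delong_compare",
    "transfer_model",
    "apoe_dosage_scores",
]


class SeparationError(RuntimeError):
    """Raised when the classes are completely separated; the MLE diverges."""


@dataclass(frozen=True)
class FeatureSpec:
    """Which features enter the model and how APOE is encoded.

    ``apoe_encoding``: ``"nominal"`` fits one indicator per carrier level
    present in training (heterozygote, homozygote vs non-carrier);
    ``"allele_count"`` enters the 0/1/2 dosage as one linear term; ``None``
    omits the genotype.
    """

    meth_regions: tuple[str, ...] = ()
    apoe_encoding: str | None = "nominal"

    def __post_init__(self) -> None:
        if self.apoe_encoding not in (None, "nominal", "allele_count"):
            raise ValueError(f"unknown apoe_encoding {self.apoe_encoding!r}")
        if not self.meth_regions and self.apoe_encoding is None:
            raise ValueError("feature spec needs at least one feature")


@dataclass
class RocResult:
    """An ROC curve with its tie-adjusted AUC and DeLong-variance CI."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    auc_variance: float
    has_ties: bool

    def __repr__(self) -> str:  # compact: arrays are long
        return (
            f"RocResult(auc={self.auc:.4f}, ci95=({self.ci95[0]:.3f}, "
            f"{self.ci95[1]:.3f}), n_pos={self.n_pos}, n_neg={self.n_neg})"
        )

    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _check_labels(labels: np.ndarray) -> np.ndarray:
    lab = np.asarray(labels)
    uniq = set(np.unique(lab).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be 0/1, got {sorted(uniq)}")
    if uniq != {0, 1}:
        raise ValueError("both classes must be present")
    return lab.astype(int)


def _midrank_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components via midranks.

    Returns (auc, v10 per case, v01 per control): v10[i] is the probability
    that case i outranks a random control (ties half-credit), and v01[j] the
    complement for control j.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_r = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and tie-adjusted AUC with a DeLong-variance 95% CI."""
    s = np.asarray(scores, dtype=float)
    lab = _check_labels(np.asarray(labels))
    if s.size != lab.size:
        raise ValueError("scores and labels must have equal length")

    auc, v10, v01 = _midrank_components(s, lab)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(auc - half, 0.0), min(auc + half, 1.0))

    # ROC points: thresholds descending, "score >= threshold -> positive".
    order = np.argsort(-s, kind="stable")
    s_sorted, lab_sorted = s[order], lab[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(lab_sorted)[distinct]
    fp = np.cumsum(1 - lab_sorted)[distinct]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    tpr = np.r_[0.0, tp / m]
    fpr = np.r_[0.0, fp / n]

    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, ci95=ci,
        n_pos=m, n_neg=n, auc_variance=float(var),
        has_ties=bool(np.unique(s).size < s.size),
    )


def delong_compare(scores_a, scores_b, labels) -> dict:
    """DeLong test for two correlated ROC curves on the same subjects.

    Returns the two AUCs, the z statistic for their difference under the
    structural-component covariance, and the two-tailed p-value.  Identical
    (or rank-identical) score vectors give z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    lab = _check_labels(np.asarray(labels))
    if a.size != b.size or a.size != lab.size:
        raise ValueError("paired scores require equal-length vectors")

    auc_a, v10_a, v01_a = _midrank_components(a, lab)
    auc_b, v10_b, v01_b = _midrank_components(b, lab)
    m, n = v10_a.size, v01_a.size
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "difference": diff,
        "z": float(z),
        "p_two_tailed": p,
    }


def apoe_dosage_scores(e4_counts) -> np.ndarray:
    """APOE epsilon-4 allele count (0/1/2) used directly as a risk score."""
    c = np.asarray(e4_counts, dtype=float)
    if not np.all(np.isin(c, [0.0, 1.0, 2.0])):
        raise ValueError("APOE e4 counts must be 0, 1 or 2")
    return c


class MethylationRiskModel:
    """Multiple logistic regression of AD status on methylation and APOE.

    Built from a cohort DataFrame with ``meth_<region>`` percent-methylation
    columns, an ``apoe_e4_count`` column, and a case/control label.
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame, spec: FeatureSpec,
                 cohort_id: str = ""):
        self.endog = _check_labels(endog)
        self.exog = exog
        self.spec = spec
        self.cohort_id = cohort_id

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        meth_regions: Sequence[str] = (),
        apoe: str | None = "nominal",
        label_col: str = "group",
        case: str = "AD",
        control: str = "Ctrl",
        cohort_id: str = "",
        _training_levels: tuple[int, ...] | None = None,
    ) -> "MethylationRiskModel":
        spec = FeatureSpec(tuple(meth_regions), apoe)
        sub = data[data[label_col].isin([case, control])]
        endog = (sub[label_col] == case).to_numpy().astype(int)
        exog = cls._design(sub, spec, _training_levels)
        keep = ~exog.isna().any(axis=1).to_numpy()
        return cls(endog[keep], exog[keep], spec, cohort_id)

    @staticmethod
    def _design(
        df: pd.DataFrame,
        spec: FeatureSpec,
        training_levels: tuple[int, ...] | None = None,
    ) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
        for region in spec.meth_regions:
            col = f"meth_{region}"
            if col not in df.columns:
                raise KeyError(f"cohort table lacks feature column {col!r}")
            cols[col] = df[col].to_numpy(dtype=float)
        if spec.apoe_encoding is not None:
            if "apoe_e4_count" not in df.columns:
                raise KeyError("cohort table lacks feature column 'apoe_e4_count'")
            e4 = df["apoe_e4_count"].to_numpy(dtype=float)
            if spec.apoe_encoding == "allele_count":
                cols["apoe_e4_count"] = e4
            else:
                levels = (
                    training_levels
                    if training_levels is not None
                    else tuple(sorted({int(v) for v in e4} - {0}))
                )
                if training_levels is None and set(np.unique(e4)) - {0} != set(levels):
                    pass  # unreachable; kept for clarity
                if 2 not in levels and np.any(e4 == 2):
                    warnings.warn(
                        "no epsilon4 homozygotes in training: collapsing "
                        "homozygotes onto the heterozygote indicator",
                        stacklevel=3,
                    )
                for lev in levels:
                    if lev == max(levels):
                        cols[f"apoe_e4_{lev}"] = (e4 >= lev).astype(float)
                    else:
                        cols[f"apoe_e4_{lev}"] = (e4 == lev).astype(float)
        return pd.DataFrame(cols, index=df.index)

    @property
    def training_apoe_levels(self) -> tuple[int, ...]:
        return tuple(
            int(c.rsplit("_", 1)[1])
            for c in self.exog.columns
            if c.startswith("apoe_e4_") and c != "apoe_e4_count"
        )

    # -- estimation -------------------------------------------------------
    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> "MethylationRiskResults":
        """Maximum-likelihood fit (Newton/IRLS); refuses complete separation.

        A degenerate genotype cell (e.g. every epsilon4 homozygote in one
        class) makes the homozygote indicator quasi-separated; in that case
        the nominal encoding is collapsed to a single carrier indicator with
        a warning and the fit retried once.
        """
        try:
            return self._fit_once(maxiter, tol)
        except SeparationError:
            cols = [c for c in self.exog.columns if c.startswith("apoe_e4_")
                    and c != "apoe_e4_count"]
            if len(cols) < 2:
                raise
            warnings.warn(
                "degenerate APOE genotype cell: collapsing nominal encoding "
                "to a single epsilon4-carrier indicator",
                stacklevel=2,
            )
            carrier = self.exog[cols].max(axis=1)
            exog = self.exog.drop(columns=cols)
            exog["apoe_e4_1"] = carrier
            collapsed = MethylationRiskModel(
                self.endog, exog, self.spec, self.cohort_id
            )
            return collapsed._fit_once(maxiter, tol)

    def _fit_once(self, maxiter: int, tol: float) -> "MethylationRiskResults":
        X = self.exog.to_numpy(dtype=float)
        for j, name in enumerate(self.exog.columns):
            if name != "const" and np.ptp(X[:, j]) == 0.0:
                raise ValueError(f"constant feature {name!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.endog, X).fit(
                    disp=0, maxiter=maxiter, tol=tol, method="newton"
                )
            except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
                raise SeparationError(str(e)) from e
        params = np.asarray(res.params, dtype=float)
        fitted = res.predict()
        eps = 1e-8
        separated = bool(
            np.all((fitted > 1 - eps) == (self.endog == 1))
            and np.all((fitted < eps) == (self.endog == 0))
            and np.all((fitted > 1 - eps) | (fitted < eps))
        )
        if separated or not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
            raise SeparationError(
                "complete separation detected: logistic MLE does not exist"
            )
        return MethylationRiskResults(self, res)


class MethylationRiskResults:
    """Fitted risk model: coefficients, uncertainties, AIC, ROC evaluation."""

    def __init__(self, model: MethylationRiskModel, smres):
        self.model = model
        self._smres = smres
        self.feature_names = list(model.exog.columns)
        self.params = pd.Series(
            np.asarray(smres.params, dtype=float), index=self.feature_names
        )
        self.bse = pd.Series(
            np.asarray(smres.bse, dtype=float), index=self.feature_names
        )
        self.llf = float(smres.llf)
        self.aic = float(smres.aic)
        self.converged = bool(smres.mle_retvals.get("converged", True))

    # -- prediction -------------------------------------------------------
    def _design_for(self, data: pd.DataFrame) -> pd.DataFrame:
        X = MethylationRiskModel._design(
            data, self.model.spec,
            training_levels=self.model.training_apoe_levels or None,
        )
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"cohort lacks model feature(s): {missing}")
        return X[self.feature_names]

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        return self._design_for(data).to_numpy(dtype=float) @ self.params.to_numpy()

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        eta = self.linear_predictor(data)
        return 1.0 / (1.0 + np.exp(-eta))

    # -- evaluation -------------------------------------------------------
    def roc(self) -> RocResult:
        """In-sample ROC of the fitted linear predictor."""
        eta = self.model.exog.to_numpy(dtype=float) @ self.params.to_numpy()
        return roc_auc(eta, self.model.endog)

    def transfer(
        self,
        data: pd.DataFrame,
        label_col: str = "group",
        case: str = "AD",
        control: str = "Ctrl",
    ) -> RocResult:
        """Apply the fitted model unchanged to an independent cohort.

        Scores are the linear predictor with the training coefficients; the
        ROC is computed against the new cohort's labels.  Rows with missing
        features are dropped.
        """
        sub = data[data[label_col].isin([case, control])].copy()
        X = self._design_for(sub)
        keep = ~X.isna().any(axis=1)
        sub, X = sub[keep], X[keep]
        labels = (sub[label_col] == case).to_numpy().astype(int)
        scores = X.to_numpy(dtype=float) @ self.params.to_numpy()
        return roc_auc(scores, labels)

    def summary(self) -> str:
        lines = [
            "Methylation + APOE logistic risk model",
            "=" * 54,
            f"cohort: {self.model.cohort_id or '<unnamed>'}   "
            f"n={len(self.model.endog)}  "
            f"(cases={int(self.model.endog.sum())})",
            f"features: {', '.join(n for n in self.feature_names if n != 'const')}",
            f"log-likelihood: {self.llf:.3f}   AIC: {self.aic:.3f}",
            "-" * 54,
            f"{'term':<20}{'coef':>10}{'std err':>10}{'z':>8}{'P>|z|':>8}",
        ]
        for name in self.feature_names:
            b, se = self.params[name], self.bse[name]
            z = b / se if se > 0 else np.nan
            p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(f"{name:<20}{b:>10.4f}{se:>10.4f}{z:>8.2f}{p:>8.4f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "cohort_id": self.model.cohort_id,
            "feature_spec": {
                "meth_regions": list(self.model.spec.meth_regions),
                "apoe_encoding": self.model.spec.apoe_encoding,
            },
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "std_errors": {k: float(v) for k, v in self.bse.items()},
            "log_likelihood": self.llf,
            "aic": self.aic,
            "converged": self.converged,
        }


# -- spec-surface convenience wrappers ------------------------------------

def fit_logistic(
    data: pd.DataFrame,
    meth_regions: Sequence[str] = (),
    apoe: str | None = "nominal",
    **kwargs,
) -> MethylationRiskResults:
    """Fit the logistic risk model; thin wrapper over the Model class."""
    return MethylationRiskModel.from_dataframe(
        data, meth_regions=meth_regions, apoe=apoe, **kwargs
    ).fit()


def stepwise_select(
    data: pd.DataFrame,
    candidate_regions: Sequence[str],
    include_apoe: bool = True,
    apoe: str = "nominal",
    criterion: str = "aic",
    label_col: str = "group",
    case: str = "AD",
    control: str = "Ctrl",
    cohort_id: str = "",
) -> tuple[FeatureSpec, MethylationRiskResults | None, list[str]]:
    """Bidirectional stepwise feature selection under AIC (or BIC).

    Candidates are methylation regions plus, optionally, the APOE genotype.
    Starting from the intercept-only model, each round tries every single
    addition and removal and keeps the move that most improves the
    criterion; the search stops when no move improves it.  Returns the
    selected spec, its fitted results (``None`` if the empty model wins,
    with a warning), and the selection path log.
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    if not candidate_regions and not include_apoe:
        raise ValueError("no candidate features")

    candidates = [("meth", r) for r in candidate_regions]
    if include_apoe:
        candidates.append(("apoe", apoe))

    def crit_of(feats: list) -> tuple[float, MethylationRiskResults | None]:
        regions = tuple(r for kind, r in feats if kind == "meth")
        use_apoe = apoe if any(k == "apoe" for k, _ in feats) else None
        sub = data[data[label_col].isin([case, control])]
        endog = (sub[label_col] == case).to_numpy().astype(int)
        if not feats:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(endog, np.ones((endog.size, 1))).fit(disp=0)
            val = res.aic if criterion == "aic" else res.bic
            return float(val), None
        try:
            fitted = fit_logistic(
                data, meth_regions=regions, apoe=use_apoe,
                label_col=label_col, case=case, control=control,
                cohort_id=cohort_id,
            )
        except (SeparationError, ValueError, KeyError):
            return np.inf, None
        if criterion == "aic":
            return fitted.aic, fitted
        k = len(fitted.params)
        n = len(fitted.model.endog)
        return float(-2 * fitted.llf + k * np.log(n)), fitted

    selected: list = []
    best_crit, best_fit = crit_of(selected)
    path = [f"start: intercept-only, {criterion}={best_crit:.3f}"]
    improved = True
    while improved:
        improved = False
        moves = [("add", c) for c in candidates if c not in selected]
        moves += [("drop", c) for c in selected]
        best_move = None
        for action, feat in moves:
            trial = (
                selected + [feat] if action == "add"
                else [f for f in selected if f != feat]
            )
            c, f = crit_of(trial)
            if c < best_crit - 1e-9:
                best_crit, best_fit, best_move = c, f, (action, feat, trial)
        if best_move:
            action, feat, trial = best_move
            selected = trial
            path.append(
                f"{action} {feat[1] if feat[0] == 'meth' else 'APOE'}: "
                f"{criterion}={best_crit:.3f}"
            )
            improved = True

    if not selected:
        warnings.warn("stepwise selection kept no feature; intercept-only model",
                      stacklevel=2)
        return _empty_spec(), None, path
    spec = FeatureSpec(
        tuple(r for k, r in selected if k == "meth"),
        apoe if any(k == "apoe" for k, _ in selected) else None,
    )
    return spec, best_fit, path


class _EmptySpec:
    """Sentinel for an empty stepwise selection (intercept-only)."""

    meth_regions: tuple = ()
    apoe_encoding = None

    def __repr__(self) -> str:
        return "FeatureSpec(<empty: intercept-only>)"


def _empty_spec() -> _EmptySpec:
    return _EmptySpec()


def transfer_model(
    results: MethylationRiskResults,
    cohort: pd.DataFrame,
    **kwargs,
) -> RocResult:
    """Spec-surface alias for :meth:`MethylationRiskResults.transfer`."""
    return results.transfer(cohort, **kwargs)
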