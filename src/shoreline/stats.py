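"""Cohort-level statistics for shore methylation differences.

The group comparisons used throughout the analysis: pooled-variance Student's
t with Bonferroni correction across assay regions, one-way ANOVA with Dunnett
(many-to-one) or Tukey (all-pairs) post-tests, Kruskal-Wallis with Dunn's
post-test for genotype-stratified methylation, Pearson correlation, and
ordinary least squares for expression-vs-methylation.

Standard tests are delegated to scipy/statsmodels; the Dunn post-test is
implemented here (rank-based z statistics with tie correction and Bonferroni
adjustment, the convention of the graphing software the field uses).  Every
operation returns :class:`TestResult` records so downstream tables are tidy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "student_t_two_group",
    "bonferroni_threshold",
    "one_way_anova",
    "dunnett_posttest",
    "tukey_posttest",
    "kruskal_wallis_dunn",
    "pearson_correlation",
    "expression_methylation_regression",
    "region_difference_screen",
]


@dataclass
class TestResult:
    """One hypothesis test: statistic, df, two-tailed p, significance flag."""

    method: str
    statistic: float
    df: float | tuple[float, float] | None
    p_two_tailed: float
    adjusted_threshold: float | None = None
    significant: bool | None = None
    comparison: str = ""
    direction: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.adjusted_threshold is not None and self.significant is None:
            self.significant = self.p_two_tailed < self.adjusted_threshold


def _as_arr(x: Iterable[float], name: str, min_n: int = 2) -> np.ndarray:
    a = np.asarray(list(x), dtype=float)
    if a.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} values, got {a.size}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def student_t_two_group(
    x: Iterable[float], y: Iterable[float], welch: bool = False
) -> TestResult:
    """Two-sample t-test, pooled-variance by default (Welch behind a flag).

    Degenerate inputs: identical constant groups give t = 0, p = 1; constant
    groups with different means are flagged degenerate (p -> 0 limit).
    """
    a, b = _as_arr(x, "x"), _as_arr(y, "y")
    n1, n2 = a.size, b.size
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult("student_t", 0.0, n1 + n2 - 2, 1.0, degenerate=True)
        return TestResult(
            "student_t", math.inf if a.mean() > b.mean() else -math.inf,
            n1 + n2 - 2, 0.0, degenerate=True,
        )
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    df = (n1 + n2 - 2) if not welch else None
    return TestResult("welch_t" if welch else "student_t", float(t), df, float(p))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m for m comparisons."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def one_way_anova(groups: Sequence[Iterable[float]]) -> TestResult:
    """One-way fixed-effects ANOVA; F with (k-1, N-k) degrees of freedom."""
    arrs = [_as_arr(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    if all(np.all(a == arrs[0][0]) for a in arrs):
        return TestResult(
            "anova", 0.0, (k - 1, n_total - k), 1.0, degenerate=True
        )
    f, p = sps.f_oneway(*arrs)
    return TestResult("anova", float(f), (k - 1, n_total - k), float(p))


def dunnett_posttest(
    control: Iterable[float],
    treatments: Sequence[Iterable[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[TestResult]:
    """Dunnett's many-to-one comparisons against a shared control.

    Familywise error is controlled through the equicoordinate multivariate-t
    critical value; the integration is stochastic, so a seed fixes the
    adjusted p-values.
    """
    ctrl = _as_arr(control, "control")
    arrs = [_as_arr(t, f"treatment {i}") for i, t in enumerate(treatments)]
    if not arrs:
        raise ValueError("need at least one treatment group")
    labels = list(labels) if labels is not None else [
        f"treatment_{i}" for i in range(len(arrs))
    ]
    res = sps.dunnett(
        *arrs, control=ctrl, random_state=np.random.default_rng(seed)
    )
    out = []
    for i, (stat, p) in enumerate(zip(res.statistic, res.pvalue)):
        diff = arrs[i].mean() - ctrl.mean()
        out.append(
            TestResult(
                "dunnett", float(stat), None, float(min(p, 1.0)),
                adjusted_threshold=alpha,
                comparison=f"{labels[i]} vs control",
                direction="higher" if diff > 0 else ("lower" if diff < 0 else "equal"),
            )
        )
    return out


def tukey_posttest(
    groups: Sequence[Iterable[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[TestResult]:
    """Tukey's HSD all-pairs comparisons (studentized-range based)."""
    arrs = [_as_arr(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    labels = list(labels) if labels is not None else [
        f"group_{i}" for i in range(len(arrs))
    ]
    res = sps.tukey_hsd(*arrs)
    out = []
    for i, j in combinations(range(len(arrs)), 2):
        diff = arrs[i].mean() - arrs[j].mean()
        out.append(
            TestResult(
                "tukey_hsd", float(res.statistic[i, j]), None,
                float(min(res.pvalue[i, j], 1.0)),
                adjusted_threshold=alpha,
                comparison=f"{labels[i]} vs {labels[j]}",
                direction="higher" if diff > 0 else ("lower" if diff < 0 else "equal"),
            )
        )
    return out


def kruskal_wallis_dunn(
    groups: Mapping[str, Iterable[float]], alpha: float = 0.05
) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise post-test.

    Dunn's z uses mean ranks from the joint ranking with the standard tie
    correction; pairwise p-values are Bonferroni-adjusted over all pairs.
    """
    keys = list(groups.keys())
    arrs = {k: _as_arr(groups[k], k, min_n=1) for k in keys}
    if len(keys) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate([arrs[k] for k in keys])
    if np.all(pooled == pooled[0]):
        omnibus = TestResult(
            "kruskal_wallis", 0.0, len(keys) - 1, 1.0, degenerate=True
        )
        return omnibus, []
    h, p = sps.kruskal(*[arrs[k] for k in keys])
    omnibus = TestResult("kruskal_wallis", float(h), len(keys) - 1, float(p))

    ranks = sps.rankdata(pooled)
    n = pooled.size
    # tie correction for the Dunn z variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    sizes, mean_ranks, pos = {}, {}, 0
    for k in keys:
        m = arrs[k].size
        sizes[k] = m
        mean_ranks[k] = ranks[pos : pos + m].mean()
        pos += m
    m_pairs = len(keys) * (len(keys) - 1) // 2
    pairwise = []
    for a, b in combinations(keys, 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1 / sizes[a] + 1 / sizes[b])
        z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var) if var > 0 else 0.0
        p_unadj = 2.0 * sps.norm.sf(abs(z))
        pairwise.append(
            TestResult(
                "dunn", float(z), None, float(min(p_unadj * m_pairs, 1.0)),
                adjusted_threshold=alpha, comparison=f"{a} vs {b}",
            )
        )
    return omnibus, pairwise


def pearson_correlation(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Pearson r with the two-tailed t-based p-value."""
    a, b = _as_arr(x, "x", 3), _as_arr(y, "y", 3)
    if a.size != b.size:
        raise ValueError("x and y must have equal length")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(a, b)
    return TestResult("pearson", float(r), a.size - 2, float(p))


def expression_methylation_regression(
    subjects: pd.DataFrame, gene: str, region: str | None = None
) -> dict:
    """OLS of normalized expression on region mean methylation.

    ``subjects`` must carry ``meth_<region>`` and ``expr_<gene>`` columns;
    rows missing either value are dropped pairwise and the retained count is
    reported.  Returns slope, intercept, Pearson r, and the two-tailed p.
    """
    region = region or gene
    mcol, ecol = f"meth_{region}", f"expr_{gene}"
    for col in (mcol, ecol):
        if col not in subjects.columns:
            raise KeyError(f"column {col!r} missing from cohort table")
    sub = subjects[[mcol, ecol]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 subjects with both values, got {n}")
    lr = sps.linregress(sub[mcol].to_numpy(), sub[ecol].to_numpy())
    return {
        "gene": gene,
        "region": region,
        "slope": float(lr.slope),
        "intercept": float(lr.intercept),
        "r": float(lr.rvalue),
        "p_two_tailed": float(lr.pvalue),
        "n_used": n,
        "n_dropped": len(subjects) - n,
    }


def region_difference_screen(
    subjects: pd.DataFrame,
    regions: Sequence[str],
    alpha: float = 0.05,
    group_col: str = "group",
    case: str = "AD",
    control: str = "Ctrl",
    m_comparisons: int | None = None,
) -> pd.DataFrame:
    """Per-region Student's t screen with a shared Bonferroni threshold.

    One pooled-variance t-test per assay region comparing case vs control
    mean methylation, thresholded at ``alpha / m`` where ``m`` defaults to
    the number of regions screened together.  Regions missing a group are
    excluded and logged in the output.  Returns a tidy results table.
    """
    m = m_comparisons if m_comparisons is not None else len(regions)
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    for region in regions:
        col = f"meth_{region}"
        if col not in subjects.columns:
            rows.append(
                {"region": region, "status": "missing column", "n_case": 0,
                 "n_control": 0}
            )
            continue
        case_v = subjects.loc[subjects[group_col] == case, col].dropna()
        ctrl_v = subjects.loc[subjects[group_col] == control, col].dropna()
        if len(case_v) < 2 or len(ctrl_v) < 2:
            rows.append(
                {"region": region, "status": "group missing", "n_case": len(case_v),
                 "n_control": len(ctrl_v)}
            )
            continue
        res = student_t_two_group(case_v, ctrl_v)
        diff = case_v.mean() - ctrl_v.mean()
        rows.append(
            {
                "region": region,
                "status": "ok",
                "n_case": len(case_v),
                "n_control": len(ctrl_v),
                "mean_case": case_v.mean(),
                "mean_control": ctrl_v.mean(),
                "difference": diff,
                "direction": "lower in case" if diff < 0 else (
                    "higher in case" if diff > 0 else "equal"
                ),
                "t": res.statistic,
                "df": res.df,
                "p_two_tailed": res.p_two_tailed,
                "bonferroni_threshold": threshold,
                "significant": res.p_two_tailed < threshold,
            }
        )
    return pd.DataFrame(rows)
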