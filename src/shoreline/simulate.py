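"""Synthetic cohorts, landscapes, clone reads and pyro tables.

Everything downstream of the wet lab is testable against planted truth:
this module generates (i) locus sequences with a planted CpG island and
density-graded shores, (ii) clone-level bisulfite reads with conversion
failures, CpG-destroying polymorphisms and sequencing errors, (iii)
pyrosequencing tables with RLU quality classes, and (iv) cohort tables whose
group sizes, age/MMSE distributions and APOE genotype frequencies follow the
study population: two case/control groups of 48+48 (test and replication)
plus DLB/VaD/FTD dementia groups.

Subject-level methylation truth is Beta-distributed around the group mean
(concentration 40 puts control SDs around 6-8 percentage points at
mid-range means); the measured value adds clone-sampling binomial noise
(20-32 clones per subject).  Disease shifts default to modest
hypomethylation, under 10 percentage points, in CR1/CLU/PICALM/TREM2 for AD
and in CLU for DLB; every other region and group is null.  All generators
are pure functions of their spec and seed.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bisulfite import Amplicon

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "LandscapeSpec",
    "generate_landscape",
    "generate_subjects",
    "generate_clone_reads",
    "generate_pyro_table",
    "generate_amplicon",
    "end_to_end_fixture",
    "DEFAULT_REGIONS",
]

DEFAULT_REGIONS = (
    "APOE", "BIN1", "PICALM", "CR1", "CLU", "ABCA7", "TREM2", "CLU_pyro",
)

# Control-group mean methylation per region (percent). The APOE shore sits
# near 50% (the classic moderately methylated shore); others span the
# 20-60% range typical of blood shores.
DEFAULT_CONTROL_MEANS = {
    "APOE": 50.0, "BIN1": 20.0, "PICALM": 40.0, "CR1": 35.0,
    "CLU": 45.0, "ABCA7": 25.0, "TREM2": 60.0, "CLU_pyro": 45.0,
}

# Disease shifts in percentage points; all magnitudes < 10.
DEFAULT_GROUP_SHIFTS = {
    "AD": {"CR1": -8.0, "CLU": -8.0, "PICALM": -8.0, "TREM2": -6.0,
           "CLU_pyro": -8.0},
    "DLB": {"CLU": -6.0, "CLU_pyro": -6.0},
    "VaD": {},
    "FTD": {},
    "Ctrl": {},
}


@dataclass(frozen=True)
class GroupSpec:
    """One clinical group: size, demographics, APOE genotype frequencies."""

    name: str
    n: int
    age_mean: float
    age_sd: float
    mmse_mean: float
    mmse_sd: float
    # P(epsilon4 count = 0, 1, 2)
    apoe_probs: tuple[float, float, float]
    female_fraction: float = 0.5
    mmse_min: float = 0.0
    mmse_max: float = 30.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if abs(sum(self.apoe_probs) - 1.0) > 1e-9:
            raise ValueError(f"APOE probabilities must sum to 1 in {self.name}")


def _study_groups() -> tuple[GroupSpec, ...]:
    """The seven demographic cells of the study population."""
    return (
        # test group
        GroupSpec("Ctrl-test", 48, 71.9, 3.7, 28.5, 1.5,
                  (38 / 48, 9 / 48, 1 / 48), 22 / 48, mmse_min=26.0),
        GroupSpec("AD-test", 48, 72.7, 5.4, 13.3, 5.1,
                  (17 / 48, 22 / 48, 9 / 48), 24 / 48),
        # replication group
        GroupSpec("Ctrl-replication", 48, 70.2, 1.5, 29.4, 0.8,
                  (42 / 48, 6 / 48, 0.0), 26 / 48, mmse_min=26.0),
        GroupSpec("AD-replication", 48, 70.5, 1.8, 17.7, 3.8,
                  (16 / 48, 28 / 48, 4 / 48), 24 / 48),
        # non-AD dementia
        GroupSpec("DLB", 34, 79.0, 5.4, 16.7, 4.7,
                  (22 / 34, 9 / 34, 3 / 34), 21 / 34),
        GroupSpec("VaD", 40, 79.0, 6.9, 17.4, 4.8,
                  (31 / 39, 7 / 39, 1 / 39), 15 / 40),
        GroupSpec("FTD", 27, 70.2, 8.8, 16.6, 6.9,
                  (17 / 27, 10 / 27, 0.0), 17 / 27),
    )


@dataclass(frozen=True)
class CohortSpec:
    """Generative spec for the synthetic cohort table."""

    groups: tuple[GroupSpec, ...] = field(default_factory=_study_groups)
    regions: tuple[str, ...] = DEFAULT_REGIONS
    control_means: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_MEANS)
    )
    group_shifts: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_SHIFTS.items()}
    )
    beta_concentration: float = 40.0
    clone_min: int = 20
    clone_max: int = 32
    cpgs_per_region: int = 10
    snp_ids: tuple[str, ...] = ("rs3818361", "rs11136000", "rs3851179")
    snp_alt_freq: float = 0.3
    expression_genes: tuple[str, ...] = ("CR1", "CLU", "PICALM")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.clone_min <= self.clone_max):
            raise ValueError("clone_min must be <= clone_max")
        for region in self.regions:
            mean = self.control_means.get(region)
            if mean is None or not (0.0 <= mean <= 100.0):
                raise ValueError(f"control mean missing/invalid for {region}")
            for g, shifts in self.group_shifts.items():
                shifted = mean + shifts.get(region, 0.0)
                if not (0.0 <= shifted <= 100.0):
                    raise ValueError(
                        f"shift for {region} in {g} leaves mean outside [0,100]"
                    )


@dataclass(frozen=True)
class LandscapeSpec:
    """Planted-truth locus: background / 2-kb shores / ~1-kb island."""

    locus_length: int = 10_000
    island_start: int = 4_500
    island_length: int = 1_000
    island_cpg_prob: float = 0.10
    island_gc: float = 0.60
    shore_length: int = 2_000
    shore_cpg_prob: float = 0.02
    shore_gc: float = 0.48
    background_cpg_prob: float = 0.004
    background_gc: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            self.island_cpg_prob > self.shore_cpg_prob > self.background_cpg_prob
        ):
            raise ValueError(
                "densities must be graded: island > shore > background"
            )
        if self.island_start < 0 or (
            self.island_start + self.island_length > self.locus_length
        ):
            raise ValueError("island outside locus")

    @property
    def island_end(self) -> int:
        return self.island_start + self.island_length


def _segment(length: int, cpg_prob: float, gc: float,
             rng: np.random.Generator) -> str:
    """Random sequence with controlled CpG density and GC content.

    CpG dinucleotides are planted explicitly at ``cpg_prob`` per position;
    incidental CpGs from the random background are suppressed (no G is
    emitted directly after a C) so the planted density is the true density.
    """
    # base composition once planted CpGs are excluded
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    probs = probs / probs.sum()
    bases = "ACGT"
    draws = rng.choice(4, size=2 * length + 4, p=probs)
    plant = rng.random(length) < cpg_prob
    out: list[str] = []
    i = d = 0
    while i < length:
        if i + 1 < length and plant[i]:
            out.append("CG")
            i += 2
            continue
        b = bases[draws[d]]
        d += 1
        if b == "G" and out and out[-1][-1] == "C":
            b = "A"  # suppress incidental CpG
        out.append(b)
        i += 1
    return "".join(out)[:length]


def generate_landscape(spec: LandscapeSpec) -> tuple[str, dict]:
    """Locus sequence with a planted island and graded shores, plus truth.

    Returns ``(sequence, truth)`` where truth records the exact planted
    island and shore intervals and the density parameters used.
    """
    rng = np.random.default_rng(spec.seed)
    up_shore_start = max(spec.island_start - spec.shore_length, 0)
    down_shore_end = min(spec.island_end + spec.shore_length, spec.locus_length)
    parts = [
        _segment(up_shore_start, spec.background_cpg_prob, spec.background_gc, rng),
        _segment(spec.island_start - up_shore_start, spec.shore_cpg_prob,
                 spec.shore_gc, rng),
        _segment(spec.island_length, spec.island_cpg_prob, spec.island_gc, rng),
        _segment(down_shore_end - spec.island_end, spec.shore_cpg_prob,
                 spec.shore_gc, rng),
        _segment(spec.locus_length - down_shore_end, spec.background_cpg_prob,
                 spec.background_gc, rng),
    ]
    seq = "".join(parts)
    truth = {
        "island": [spec.island_start, spec.island_end],
        "shores": [
            [up_shore_start, spec.island_start],
            [spec.island_end, down_shore_end],
        ],
        "locus_length": spec.locus_length,
        "densities": {
            "island_cpg_prob": spec.island_cpg_prob,
            "shore_cpg_prob": spec.shore_cpg_prob,
            "background_cpg_prob": spec.background_cpg_prob,
        },
        "seed": spec.seed,
    }
    return seq, truth


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are narrow only for MMSE)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def generate_subjects(spec: CohortSpec | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Cohort table with demographics, genotypes and measured methylation.

    ``meth_<region>`` is the clone-sampled measurement (binomial over
    ``n_clones x cpgs_per_region`` scorable calls around the subject's true
    Beta-distributed rate); ``true_meth_<region>`` keeps the latent truth so
    recovery can be tested.  Controls always have MMSE > 25.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    sid = 0
    for g in spec.groups:
        base_group = g.name.split("-")[0]
        cohort = g.name.split("-")[1] if "-" in g.name else "dementia"
        ages = rng.normal(g.age_mean, g.age_sd, size=g.n)
        mmse = _truncnorm(rng, g.mmse_mean, g.mmse_sd, g.mmse_min, g.mmse_max, g.n)
        e4 = rng.choice([0, 1, 2], size=g.n, p=g.apoe_probs)
        female = rng.random(g.n) < g.female_fraction
        clone_counts = rng.integers(spec.clone_min, spec.clone_max + 1,
                                    size=(g.n, len(spec.regions)))
        for i in range(g.n):
            sid += 1
            row = {
                "subject_id": f"S{sid:04d}",
                "group": base_group,
                "cohort": cohort,
                "age": round(float(ages[i]), 1),
                "sex": "F" if female[i] else "M",
                "mmse": int(round(mmse[i])),
                "apoe_e4_count": int(e4[i]),
            }
            for rs in spec.snp_ids:
                p = spec.snp_alt_freq
                gt = rng.choice(
                    ["ref/ref", "ref/alt", "alt/alt"],
                    p=[(1 - p) ** 2, 2 * p * (1 - p), p**2],
                )
                row[f"snp_{rs}"] = gt
            for j, region in enumerate(spec.regions):
                mean = (
                    spec.control_means[region]
                    + spec.group_shifts.get(base_group, {}).get(region, 0.0)
                ) / 100.0
                mean = min(max(mean, 1e-6), 1 - 1e-6)
                a = mean * spec.beta_concentration
                b = (1 - mean) * spec.beta_concentration
                true_rate = rng.beta(a, b)
                n_calls = int(clone_counts[i, j]) * spec.cpgs_per_region
                measured = 100.0 * rng.binomial(n_calls, true_rate) / n_calls
                row[f"true_meth_{region}"] = round(100.0 * true_rate, 3)
                row[f"meth_{region}"] = round(measured, 3)
                row[f"n_clones_{region}"] = int(clone_counts[i, j])
            # expression independent of methylation (the study's null finding)
            for gene in spec.expression_genes:
                row[f"expr_{gene}"] = round(float(rng.normal(10.0, 2.0)), 3)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_amplicon(
    n_cpgs: int = 10,
    spacing: int = 30,
    gc: float = 0.45,
    seed: int = 0,
    amplicon_id: str = "amp1",
    gene_id: str = "",
    region_label: str = "",
) -> Amplicon:
    """A synthetic shore amplicon: ``n_cpgs`` CpGs roughly ``spacing`` bp apart."""
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(n_cpgs):
        spacer = _segment(spacing, 0.0, gc, rng)
        # avoid accidental CpGs at the spacer/CG junctions
        spacer = spacer.replace("CG", "CT")
        if spacer.endswith("C"):
            spacer = spacer[:-1] + "A"
        parts.append(spacer)
        parts.append("CG")
    tail = _segment(spacing, 0.0, gc, rng).replace("CG", "CT")
    if tail.startswith("G"):
        tail = "A" + tail[1:]
    parts.append(tail)
    return Amplicon(
        id=amplicon_id, ref_seq="".join(parts),
        gene_id=gene_id, region_label=region_label,
    )


def generate_clone_reads(
    amplicon: Amplicon,
    true_rate: float,
    n_clones: int,
    rng: np.random.Generator,
    conversion_failure_rate: float = 0.02,
    seq_error_rate: float = 0.001,
    snp_cpg_index: int | None = None,
    snp_clone_indices: tuple[int, ...] | None = None,
    snp_heterozygous: bool = True,
) -> tuple[list[tuple[str, str]], dict]:
    """Simulated bisulfite clone reads for one subject at one amplicon.

    Each clone draws an independent Bernoulli methylation state per CpG at
    ``true_rate``, is bisulfite-converted with per-cytosine failure at
    ``conversion_failure_rate`` (a failed non-CpG C stays C), optionally
    carries a CpG-destroying polymorphism (the G of CpG ``snp_cpg_index``
    mutated to A on the affected allele), and receives uniform substitution
    errors at ``seq_error_rate``.  Returns ``(records, truth)`` where records
    are ``(clone_id, sequence)`` pairs and truth logs every planted state.
    """
    if not (0.0 <= true_rate <= 1.0):
        raise ValueError("true_rate must be in [0, 1]")
    if amplicon.n_cpgs == 0:
        raise ValueError("amplicon has no CpG")
    ref = amplicon.ref_seq
    cpg_set = set(amplicon.cpg_offsets)

    if snp_cpg_index is not None and snp_clone_indices is None:
        if snp_heterozygous:
            snp_clone_indices = tuple(
                i for i in range(n_clones) if rng.random() < 0.5
            )
        else:
            snp_clone_indices = tuple(range(n_clones))
    snp_clones = set(snp_clone_indices or ())

    records = []
    truth_states = []
    for k in range(n_clones):
        states = rng.random(amplicon.n_cpgs) < true_rate
        has_snp = snp_cpg_index is not None and k in snp_clones
        out = []
        i = 0
        cpg_idx = {p: j for j, p in enumerate(amplicon.cpg_offsets)}
        while i < len(ref):
            b = ref[i]
            if i in cpg_set:
                j = cpg_idx[i]
                if has_snp and j == snp_cpg_index:
                    # destroyed CpG: unmethylated C (converts) + G->A
                    out.append("T")
                    out.append("A")
                else:
                    out.append("C" if states[j] else "T")
                    out.append("G")
                i += 2
                continue
            if b == "C":
                if rng.random() < conversion_failure_rate:
                    out.append("C")  # conversion failure
                else:
                    out.append("T")
            else:
                out.append(b)
            i += 1
        seq = list("".join(out))
        n_err = rng.binomial(len(seq), seq_error_rate)
        err_pos = rng.choice(len(seq), size=n_err, replace=False)
        for p in err_pos:
            alternatives = [x for x in "ACGT" if x != seq[p]]
            seq[p] = alternatives[int(rng.integers(3))]
        records.append((f"clone_{k:03d}", "".join(seq)))
        truth_states.append(states.tolist())

    truth = {
        "true_rate": true_rate,
        "states": truth_states,
        "snp_cpg_index": snp_cpg_index,
        "snp_clones": sorted(snp_clones),
        "conversion_failure_rate": conversion_failure_rate,
        "seq_error_rate": seq_error_rate,
    }
    return records, truth


def generate_pyro_table(
    true_rates: dict[str, float],
    n_cpgs: int,
    rng: np.random.Generator,
    amplicon_id: str = "TREM2_shore",
    noise_sd: float = 4.0,
    quality_fractions: tuple[float, float, float] = (0.9, 0.08, 0.02),
) -> pd.DataFrame:
    """Pyrosequencing result table with per-CpG percents and RLU scores.

    ``true_rates`` maps subject id to the latent methylation fraction.  RLU
    values are drawn so quality classes appear at ``quality_fractions``
    (blue, yellow, red): blue uniform on [20, 60), yellow [10, 20), red
    [1, 10).
    """
    if abs(sum(quality_fractions) - 1.0) > 1e-9:
        raise ValueError("quality fractions must sum to 1")
    rows = []
    for subject_id, rate in true_rates.items():
        for c in range(n_cpgs):
            pct = float(np.clip(100.0 * rate + rng.normal(0.0, noise_sd), 0, 100))
            cls = rng.choice(3, p=quality_fractions)
            if cls == 0:
                rlu = rng.uniform(20.0, 60.0)
            elif cls == 1:
                rlu = rng.uniform(10.0, 20.0)
            else:
                rlu = rng.uniform(1.0, 10.0)
            rows.append(
                {
                    "subject_id": subject_id,
                    "amplicon_id": amplicon_id,
                    "cpg_index": c,
                    "percent_meth": round(pct, 2),
                    "rlu": round(float(rlu), 2),
                }
            )
    return pd.DataFrame(rows)


def end_to_end_fixture(
    master_seed: int,
    out_dir: str | Path,
    n_clone_subjects: int = 4,
    cohort_spec: CohortSpec | None = None,
    landscape_spec: LandscapeSpec | None = None,
) -> Path:
    """Materialize a complete synthetic input set under ``out_dir``.

    Writes the landscape FASTA + truth JSON, an amplicon FASTA, clone FASTA
    files for ``n_clone_subjects`` subjects, a pyro CSV, the cohort CSV, and
    ``manifest.json`` recording every planted truth value.  The directory is
    removed again on partial failure; the same master seed always produces
    byte-identical files.
    """
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        ss = np.random.SeedSequence(master_seed)
        s_land, s_cohort, s_clone, s_pyro = [
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
        ]

        lspec = landscape_spec or LandscapeSpec(seed=s_land)
        seq, land_truth = generate_landscape(lspec)
        _write_fasta(out / "landscape.fasta", [("locus", seq)])
        (out / "landscape_truth.json").write_text(
            json.dumps(land_truth, indent=2) + "\n"
        )

        cspec = cohort_spec or CohortSpec(seed=s_cohort)
        cohort = generate_subjects(cspec)
        cohort.to_csv(out / "cohort.csv", index=False)

        amp = generate_amplicon(
            n_cpgs=cspec.cpgs_per_region, seed=s_clone,
            amplicon_id="CLU_shore_amp", gene_id="CLU", region_label="II",
        )
        _write_fasta(out / "amplicon.fasta", [(amp.id, amp.ref_seq)])

        rng = np.random.default_rng(s_clone)
        clone_truth = {}
        clones_dir = out / "clones"
        clones_dir.mkdir(exist_ok=True)
        subjects = cohort.head(n_clone_subjects)
        for _, row in subjects.iterrows():
            rate = row["true_meth_CLU"] / 100.0
            n_clones = int(row["n_clones_CLU"])
            recs, truth = generate_clone_reads(amp, rate, n_clones, rng)
            _write_fasta(clones_dir / f"{row.subject_id}.fasta", recs)
            clone_truth[row.subject_id] = truth

        rng_p = np.random.default_rng(s_pyro)
        pyro_rates = {
            r.subject_id: r["true_meth_TREM2"] / 100.0
            for _, r in cohort.iterrows()
        }
        pyro = generate_pyro_table(pyro_rates, n_cpgs=5, rng=rng_p)
        pyro.to_csv(out / "pyro.csv", index=False)

        manifest = {
            "master_seed": master_seed,
            "landscape_truth": land_truth,
            "amplicon": {"id": amp.id, "n_cpgs": amp.n_cpgs,
                         "length": len(amp.ref_seq)},
            "clone_truth": clone_truth,
            "cohort": {
                "n_subjects": len(cohort),
                "groups": cohort.groupby(["group", "cohort"]).size()
                .reset_index(name="n").to_dict("records"),
                "regions": list(cspec.regions),
                "control_means": cspec.control_means,
                "group_shifts": cspec.group_shifts,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except BaseException:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
    return out


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
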