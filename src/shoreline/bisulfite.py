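"""Clone bisulfite sequencing quantification and pyrosequencing QC.

Implements the standard clone-based workflow: each Sanger-sequenced clone is
globally aligned against the unconverted amplicon reference with a
bisulfite-asymmetric substitution rule (reference C vs clone T scores as a
match, because bisulfite converts unmethylated C to T; the reverse, reference
T vs clone C, is an ordinary mismatch).  Per-CpG calls are then read off the
alignment: C = methylated, T = unmethylated, anything else (gap, mutated G of
the CpG) = absent, the state produced by CpG-destroying polymorphisms.

Amplicon-level methylation is the pooled-call ratio
``100 * methylated / (methylated + unmethylated)`` over all passing clones,
with absent calls excluded; a profile is reportable only when at least
``min_clones`` (default 20) clones survive QC.

The pyrosequencing side applies the instrument's RLU quality classes:
blue (RLU >= 20, high quality), yellow (10 <= RLU < 20, intermediate),
red (RLU < 10, failed).  A run is accepted only when every CpG is blue or
yellow; any red call flags the sample for re-assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

__all__ = [
    "Amplicon",
    "CloneAlignment",
    "MethylationProfile",
    "PyroCall",
    "QCThresholds",
    "bisulfite_convert",
    "align_clone",
    "conversion_rate",
    "qc_filter_clones",
    "summarize_profile",
    "classify_rlu",
    "accept_pyro_run",
]

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
ABSENT = "absent"

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_SCORE = -2.0


@dataclass(frozen=True)
class Amplicon:
    """A PCR target region with its unconverted reference sequence."""

    id: str
    ref_seq: str
    gene_id: str = ""
    region_label: str = ""
    cpg_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seq = self.ref_seq.upper()
        object.__setattr__(self, "ref_seq", seq)
        if not self.cpg_offsets:
            offsets = []
            p = seq.find("CG")
            while p != -1:
                offsets.append(p)
                p = seq.find("CG", p + 1)
            object.__setattr__(self, "cpg_offsets", tuple(offsets))
        for p in self.cpg_offsets:
            if seq[p : p + 2] != "CG":
                raise ValueError(f"cpg_offset {p} does not index a CpG in {self.id}")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    def non_cpg_c_offsets(self) -> tuple[int, ...]:
        cpg = set(self.cpg_offsets)
        return tuple(
            i for i, b in enumerate(self.ref_seq) if b == "C" and i not in cpg
        )


@dataclass
class CloneAlignment:
    """One clone aligned to its amplicon, with per-CpG methylation calls."""

    clone_id: str
    amplicon_id: str
    score: float
    identity: float
    conversion_rate: float | None
    calls: tuple[str, ...]
    strand: str  # orientation used: "+" as given, "-" reverse complement
    ref_to_base: dict[int, str] = field(repr=False, default_factory=dict)

    @property
    def n_methylated(self) -> int:
        return sum(c == METHYLATED for c in self.calls)

    @property
    def n_unmethylated(self) -> int:
        return sum(c == UNMETHYLATED for c in self.calls)


@dataclass
class MethylationProfile:
    """Per-subject, per-amplicon summary over QC-passing clones."""

    subject_id: str
    amplicon_id: str
    calls: list[tuple[str, ...]]
    n_clones_pass: int
    mean_methylation: float | None
    per_cpg_methylation: tuple[float, ...]
    mean_of_clone_means: float | None
    reportable: bool
    min_clones: int = 20


@dataclass(frozen=True)
class PyroCall:
    cpg_index: int
    percent_meth: float
    rlu: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_meth <= 100.0):
            raise ValueError("percent_meth must be in [0, 100]")
        if self.rlu < 0:
            raise ValueError("rlu must be >= 0")

    @property
    def quality(self) -> str:
        return classify_rlu(self.rlu)


@dataclass(frozen=True)
class QCThresholds:
    min_identity: float = 0.90
    min_conversion: float = 0.95

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_conversion):
            if not (0.0 <= v <= 1.0):
                raise ValueError("QC thresholds must be in [0, 1]")


def bisulfite_convert(ref_seq: str, methylation_state: str) -> str:
    """In-silico bisulfite conversion of the plus strand.

    Every non-CpG cytosine becomes T.  CpG cytosines stay C under
    ``all_methylated`` and become T under ``all_unmethylated``.
    """
    if methylation_state not in ("all_methylated", "all_unmethylated"):
        raise ValueError(f"unknown methylation_state {methylation_state!r}")
    seq = ref_seq.upper()
    out = []
    for i, b in enumerate(seq):
        if b != "C":
            out.append(b)
        elif seq[i : i + 2] == "CG" and methylation_state == "all_methylated":
            out.append("C")
        else:
            out.append("T")
    return "".join(out)


def _bisulfite_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = MATCH_SCORE if a == b else MISMATCH_SCORE
    m["C", "T"] = MATCH_SCORE  # bisulfite: unmethylated/converted C reads as T
    for b in "ACGTN":
        m["N", b] = 0.0
        m[b, "N"] = 0.0
    return m


_MATRIX = _bisulfite_matrix()


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    # End gaps are free: clones may cover only part of the amplicon.
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    else:  # older attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def _align_one(ref: str, clone: str) -> tuple[float, str, str]:
    aln = _ALIGNER.align(ref, clone)[0]
    return aln.score, str(aln[0]), str(aln[1])


def align_clone(
    clone_seq: str,
    amplicon: Amplicon,
    clone_id: str = "",
    min_identity_floor: float = 0.5,
) -> CloneAlignment:
    """Bisulfite-aware global alignment of one clone with per-CpG calls.

    The clone is tried in the given orientation and as its reverse complement
    (cloned inserts are unoriented); the higher-scoring alignment wins.
    Raises ``ValueError`` when identity falls below ``min_identity_floor`` —
    such a read is not a product of this amplicon.
    """
    clone = clone_seq.upper()
    if not clone:
        raise ValueError("empty clone sequence")
    ref = amplicon.ref_seq

    fwd = _align_one(ref, clone)
    rev = _align_one(ref, reverse_complement(clone))
    (score, gref, gclone), strand = max(
        [(fwd, "+"), (rev, "-")], key=lambda t: t[0][0]
    )

    # Column walk: map each reference offset to the clone base (or "-").
    ref_to_base: dict[int, str] = {}
    rpos = 0
    cols: list[tuple[str, str]] = []
    for rb, cb in zip(gref, gclone):
        if rb != "-":
            ref_to_base[rpos] = cb
            rpos += 1
        cols.append((rb, cb))

    # Identity over the clone-covered span (end gaps excluded, internal count).
    first = next((i for i, (_, cb) in enumerate(cols) if cb != "-"), 0)
    last = next(
        (i for i in range(len(cols) - 1, -1, -1) if cols[i][1] != "-"), len(cols) - 1
    )
    span = cols[first : last + 1]
    n_match = sum(
        1
        for rb, cb in span
        if rb != "-" and cb != "-" and (rb == cb or (rb == "C" and cb == "T"))
    )
    identity = n_match / len(span) if span else 0.0
    if identity < min_identity_floor:
        raise ValueError(
            f"clone {clone_id or '<unnamed>'} identity {identity:.2f} below "
            f"floor {min_identity_floor}: not a product of amplicon {amplicon.id}"
        )

    calls = []
    for p in amplicon.cpg_offsets:
        base_c = ref_to_base.get(p, "-")
        base_g = ref_to_base.get(p + 1, "-")
        if base_g != "G":
            calls.append(ABSENT)  # CpG destroyed (polymorphism) or not covered
        elif base_c == "C":
            calls.append(METHYLATED)
        elif base_c == "T":
            calls.append(UNMETHYLATED)
        else:
            calls.append(ABSENT)

    aln = CloneAlignment(
        clone_id=clone_id,
        amplicon_id=amplicon.id,
        score=score,
        identity=identity,
        conversion_rate=None,
        calls=tuple(calls),
        strand=strand,
        ref_to_base=ref_to_base,
    )
    aln.conversion_rate = conversion_rate(aln, amplicon)
    return aln


def conversion_rate(alignment: CloneAlignment, amplicon: Amplicon) -> float | None:
    """Fraction of covered non-CpG reference cytosines read as T.

    A retained C at a non-CpG position marks a bisulfite conversion failure.
    Positions covered by neither C nor T (sequencing error, gap) are not
    informative and are excluded.  Returns ``None`` when no non-CpG C is
    covered — conversion cannot be assessed for such a clone.
    """
    n_t = n_c = 0
    for p in amplicon.non_cpg_c_offsets():
        base = alignment.ref_to_base.get(p, "-")
        if base == "T":
            n_t += 1
        elif base == "C":
            n_c += 1
    total = n_t + n_c
    return n_t / total if total else None


def qc_filter_clones(
    alignments: list[CloneAlignment],
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[CloneAlignment], list[tuple[CloneAlignment, str]]]:
    """Deterministic QC partition into (passing, rejected-with-reasons)."""
    passing: list[CloneAlignment] = []
    rejected: list[tuple[CloneAlignment, str]] = []
    for aln in alignments:
        if aln.identity < thresholds.min_identity:
            rejected.append(
                (aln, f"low identity ({aln.identity:.3f} < {thresholds.min_identity})")
            )
        elif (
            aln.conversion_rate is not None
            and aln.conversion_rate < thresholds.min_conversion
        ):
            rejected.append(
                (
                    aln,
                    f"incomplete conversion ({aln.conversion_rate:.3f} < "
                    f"{thresholds.min_conversion})",
                )
            )
        else:
            passing.append(aln)
    return passing, rejected


def summarize_profile(
    alignments: list[CloneAlignment],
    subject_id: str = "",
    min_clones: int = 20,
) -> MethylationProfile:
    """Pool QC-passing clones of one subject x amplicon into a profile.

    ``mean_methylation`` is the pooled-call ratio (total methylated over
    total scorable calls); the mean of per-clone means is reported alongside.
    Fewer than ``min_clones`` clones makes the profile unreportable, but the
    numbers are still computed for diagnostics.
    """
    if not alignments:
        return MethylationProfile(
            subject_id, "", [], 0, None, (), None, False, min_clones
        )
    amplicon_ids = {a.amplicon_id for a in alignments}
    if len(amplicon_ids) > 1:
        raise ValueError(f"clones from multiple amplicons: {sorted(amplicon_ids)}")

    calls = [a.calls for a in alignments]
    n_cpgs = len(calls[0])
    meth = np.array(
        [[c == METHYLATED for c in row] for row in calls], dtype=float
    )
    scorable = np.array(
        [[c != ABSENT for c in row] for row in calls], dtype=float
    )
    total_meth = meth.sum()
    total_scorable = scorable.sum()
    mean = 100.0 * total_meth / total_scorable if total_scorable else None

    per_cpg = []
    for j in range(n_cpgs):
        s = scorable[:, j].sum()
        per_cpg.append(100.0 * meth[:, j].sum() / s if s else float("nan"))

    clone_means = []
    for i in range(len(calls)):
        s = scorable[i].sum()
        if s:
            clone_means.append(100.0 * meth[i].sum() / s)
    mcm = float(np.mean(clone_means)) if clone_means else None

    n = len(alignments)
    return MethylationProfile(
        subject_id=subject_id,
        amplicon_id=alignments[0].amplicon_id,
        calls=calls,
        n_clones_pass=n,
        mean_methylation=mean,
        per_cpg_methylation=tuple(per_cpg),
        mean_of_clone_means=mcm,
        reportable=n >= min_clones,
        min_clones=min_clones,
    )


def classify_rlu(rlu: float) -> str:
    """Pyrosequencing quality class from the relative light unit signal."""
    if rlu < 0:
        raise ValueError("rlu must be >= 0")
    if rlu >= 20:
        return "blue"
    if rlu >= 10:
        return "yellow"
    return "red"


def accept_pyro_run(calls: list[PyroCall]) -> tuple[bool, float | None]:
    """Accept a pyrosequencing run only if no CpG scored red.

    Accepted runs return the mean of per-CpG percent methylation; a red call
    anywhere flags the sample for re-assay (returns ``(False, None)``).
    """
    if not calls:
        raise ValueError("empty pyrosequencing call list")
    if any(c.quality == "red" for c in calls):
        return False, None
    return True, float(np.mean([c.percent_meth for c in calls]))
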