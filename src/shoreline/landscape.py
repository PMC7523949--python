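"""CpG landscape of a gene locus: CpG mapping, island detection, shore delineation.

A gene locus is the gene body plus configurable upstream/downstream padding
(default 2 kb each side), always handled on the displayed (coding) strand.
Coordinates are 0-based half-open internally; the biological +1/-1 convention
(transcription start site = +1, no position 0) exists only at the display
layer (:func:`to_display_coordinates`).

CpG islands are detected with Gardiner-Garden-style sliding-window criteria
(length >= 200 bp, GC fraction >= 0.50, observed/expected CpG >= 0.60); the
thresholds are explicit parameters.  Shores are the 2-kb flanks of each
island, clipped at the locus boundary and truncated at neighbouring islands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "GeneModel",
    "CpGMap",
    "CpGIsland",
    "ShoreRegion",
    "AssayRegion",
    "IslandParams",
    "map_cpg_sites",
    "detect_cpg_islands",
    "delineate_shores",
    "select_assay_regions",
    "to_display_coordinates",
    "display_to_offset",
    "analyze_locus",
    "landscape_summary",
]

_VALID = set("ACGTN")

SHORE_LENGTH = 2000


@dataclass(frozen=True)
class GeneModel:
    """Gene structure on the displayed (coding) strand.

    ``tss`` and ``exons`` are genomic positions; the locus window spans
    ``[exons[0][0] - pad_upstream, exons[-1][1] + pad_downstream)``.
    Minus-strand genes are expected to have been flipped onto the coding
    strand at load time (see :mod:`shoreline.io`).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]
    pad_upstream: int = 2000
    pad_downstream: int = 2000

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pad_upstream < 0 or self.pad_downstream < 0:
            raise ValueError("pads must be >= 0")
        exons = tuple(tuple(e) for e in self.exons)
        if not exons:
            raise ValueError("gene model needs at least one exon")
        for (s, e) in exons:
            if e <= s:
                raise ValueError(f"empty exon ({s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be sorted and non-overlapping")
        object.__setattr__(self, "exons", exons)

    @property
    def locus_start(self) -> int:
        return self.exons[0][0] - self.pad_upstream

    @property
    def locus_end(self) -> int:
        return self.exons[-1][1] + self.pad_downstream

    @property
    def locus_length(self) -> int:
        return self.locus_end - self.locus_start

    @property
    def tss_offset(self) -> int:
        """Offset of the TSS within the locus window."""
        return self.tss - self.locus_start

    def exon_offsets(self) -> list[tuple[int, int]]:
        return [(s - self.locus_start, e - self.locus_start) for s, e in self.exons]


@dataclass(frozen=True)
class CpGMap:
    """Positions (0-based locus offsets of the C) of every CpG dinucleotide."""

    region_length: int
    positions: tuple[int, ...]

    def count_in(self, start: int, end: int) -> int:
        """Number of CpGs whose C lies in [start, end)."""
        import bisect

        return bisect.bisect_left(self.positions, end) - bisect.bisect_left(
            self.positions, start
        )


@dataclass(frozen=True)
class CpGIsland:
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    cpg_count: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def cpg_density(self) -> float:
        """CpGs per 100 bp."""
        return 100.0 * self.cpg_count / self.length


@dataclass(frozen=True)
class ShoreRegion:
    island: CpGIsland
    side: str  # "upstream" | "downstream"
    start: int
    end: int
    clipped: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AssayRegion:
    start: int
    end: int
    cpg_count: int
    cpg_density: float  # CpGs per 100 bp
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class IslandParams:
    """Sliding-window CpG island criteria (classical promoter-island defaults)."""

    min_length: int = 200
    min_gc: float = 0.50
    min_obs_exp: float = 0.60
    window: int = 200

    def __post_init__(self) -> None:
        if self.min_length <= 0 or self.window <= 0:
            raise ValueError("min_length and window must be positive")
        if not (0 < self.min_gc <= 1) or self.min_obs_exp < 0:
            raise ValueError("invalid composition thresholds")


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return seq


def map_cpg_sites(sequence: str) -> CpGMap:
    """Locate every CpG dinucleotide; N never pairs into a CpG.

    Returns the 0-based offsets of the C of each ``CG``.  An empty sequence
    yields an empty map.
    """
    seq = _check_sequence(sequence)
    positions = []
    start = 0
    while True:
        p = seq.find("CG", start)
        if p == -1:
            break
        positions.append(p)
        start = p + 1
    return CpGMap(region_length=len(seq), positions=tuple(positions))


def _window_stats(seq: str, start: int, end: int) -> tuple[float, float, int]:
    """(gc_fraction, obs/exp CpG, cpg_count) for seq[start:end)."""
    sub = seq[start:end]
    n = len(sub)
    c = sub.count("C")
    g = sub.count("G")
    cpg = sub.count("CG")
    gc = (c + g) / n if n else 0.0
    # observed/expected CpG = n_CpG * N / (n_C * n_G)
    oe = cpg * n / (c * g) if c > 0 and g > 0 else 0.0
    return gc, oe, cpg


def _window_qualifies(seq: str, start: int, end: int, p: IslandParams) -> bool:
    gc, oe, _ = _window_stats(seq, start, end)
    return gc >= p.min_gc and oe >= p.min_obs_exp


def detect_cpg_islands(
    sequence: str, params: IslandParams | None = None
) -> list[CpGIsland]:
    """Detect CpG islands as maximal merged runs of qualifying windows.

    Every window of ``params.window`` bp meeting the GC and observed/expected
    CpG thresholds marks its span; overlapping/adjacent qualifying spans are
    merged, composition is recomputed on each merged span, and spans shorter
    than ``min_length`` are dropped.  Returns sorted, non-overlapping islands.
    """
    p = params or IslandParams()
    seq = _check_sequence(sequence)
    w = p.window
    if len(seq) < w:
        import warnings

        warnings.warn(
            f"sequence length {len(seq)} < window {w}; no islands detectable",
            stacklevel=2,
        )
        return []

    # Incremental single pass over all windows.
    spans: list[list[int]] = []
    c = seq[:w].count("C")
    g = seq[:w].count("G")
    cpg = seq[:w].count("CG")
    n_windows = len(seq) - w + 1
    for i in range(n_windows):
        if i > 0:
            out_b, in_b = seq[i - 1], seq[i + w - 1]
            c += (in_b == "C") - (out_b == "C")
            g += (in_b == "G") - (out_b == "G")
            cpg += (seq[i + w - 2 : i + w] == "CG") - (seq[i - 1 : i + 1] == "CG")
        gc = (c + g) / w
        oe = cpg * w / (c * g) if c > 0 and g > 0 else 0.0
        if gc >= p.min_gc and oe >= p.min_obs_exp:
            if spans and i <= spans[-1][1]:
                spans[-1][1] = i + w
            else:
                spans.append([i, i + w])

    islands = []
    for start, end in spans:
        if end - start < p.min_length:
            continue
        gc, oe, cpg_n = _window_stats(seq, start, end)
        islands.append(
            CpGIsland(start=start, end=end, gc_fraction=gc, obs_exp_cpg=oe, cpg_count=cpg_n)
        )
    return islands


def delineate_shores(
    island: CpGIsland,
    locus_length: int,
    neighbors: Sequence[CpGIsland] = (),
    shore_length: int = SHORE_LENGTH,
) -> tuple[ShoreRegion, ShoreRegion]:
    """The 2-kb flanks of an island, clipped to the locus and at neighbours.

    The upstream shore is ``[island.start - shore_length, island.start)`` and
    the downstream shore ``[island.end, island.end + shore_length)``; either
    is truncated at the locus boundary or at the nearest neighbouring island,
    with ``clipped`` set whenever truncation occurred.
    """
    if not (0 <= island.start < island.end <= locus_length):
        raise ValueError("island outside locus")

    up_start = island.start - shore_length
    up_clip = up_start < 0
    up_start = max(up_start, 0)
    down_end = island.end + shore_length
    down_clip = down_end > locus_length
    down_end = min(down_end, locus_length)

    for nb in neighbors:
        if nb.start == island.start and nb.end == island.end:
            continue
        if nb.end <= island.start and nb.end > up_start:
            up_start = nb.end
            up_clip = True
        if nb.start >= island.end and nb.start < down_end:
            down_end = nb.start
            down_clip = True

    upstream = ShoreRegion(island, "upstream", up_start, island.start, up_clip)
    downstream = ShoreRegion(island, "downstream", island.end, down_end, down_clip)
    return upstream, downstream


def select_assay_regions(
    cpg_map: CpGMap,
    island: CpGIsland,
    shores: Sequence[ShoreRegion],
    min_cpgs: int = 5,
    max_span_bp: int = 450,
    density_ratio_max: float = 0.5,
) -> list[AssayRegion]:
    """Candidate amplicon windows inside the shores.

    A candidate is a window of at most ``max_span_bp`` (the practical Sanger
    amplicon scale) lying inside a shore, containing at least ``min_cpgs``
    CpGs, with CpG density at most ``density_ratio_max`` times the island's —
    i.e. CpG-containing but notably less dense than the island itself.  One
    best window per shore is returned, ranked by proximity to the island.
    """
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    island_density = island.cpg_density
    out: list[AssayRegion] = []
    for shore in shores:
        cpgs = [p for p in cpg_map.positions if shore.start <= p < shore.end]
        best: AssayRegion | None = None
        best_dist = None
        # Anchor candidate windows on runs of consecutive CpGs.
        for i in range(len(cpgs)):
            for j in range(i + min_cpgs - 1, len(cpgs)):
                lo, hi = cpgs[i], cpgs[j] + 2
                if hi - lo > max_span_bp:
                    break
                n = j - i + 1
                density = 100.0 * n / (hi - lo)
                if island_density > 0 and density > density_ratio_max * island_density:
                    continue
                dist = (
                    island.start - hi
                    if shore.side == "upstream"
                    else lo - island.end
                )
                cand = AssayRegion(lo, hi, n, density)
                if best is None or dist < best_dist or (
                    dist == best_dist and n > best.cpg_count
                ):
                    best, best_dist = cand, dist
        if best is not None:
            out.append(best)
    out.sort(key=lambda r: min(abs(island.start - r.end), abs(r.start - island.end)))
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    return [
        AssayRegion(r.start, r.end, r.cpg_count, r.cpg_density,
                    label=roman[i] if i < len(roman) else str(i + 1))
        for i, r in enumerate(out)
    ]


def to_display_coordinates(offset: int, gene_model: GeneModel) -> int:
    """Locus offset -> signed biological position (TSS = +1, no position 0)."""
    if not (0 <= offset < gene_model.locus_length):
        raise ValueError(f"offset {offset} outside locus [0, {gene_model.locus_length})")
    delta = offset - gene_model.tss_offset
    return delta + 1 if delta >= 0 else delta


def display_to_offset(position: int, gene_model: GeneModel) -> int:
    """Inverse of :func:`to_display_coordinates`."""
    if position == 0:
        raise ValueError("there is no biological position 0")
    delta = position - 1 if position > 0 else position
    offset = delta + gene_model.tss_offset
    if not (0 <= offset < gene_model.locus_length):
        raise ValueError(f"position {position} outside locus")
    return offset


@dataclass
class GeneLandscape:
    """Complete landscape of one locus: CpGs, islands, shores, assay regions."""

    gene_model: GeneModel
    cpg_map: CpGMap
    islands: list[CpGIsland]
    shores: list[ShoreRegion] = field(default_factory=list)
    assay_regions: list[AssayRegion] = field(default_factory=list)


def analyze_locus(
    sequence: str,
    gene_model: GeneModel,
    island_params: IslandParams | None = None,
    min_cpgs: int = 5,
    max_span_bp: int = 450,
    density_ratio_max: float = 0.5,
) -> GeneLandscape:
    """Run the full landscape workflow on one locus sequence."""
    if len(sequence) != gene_model.locus_length:
        raise ValueError(
            f"sequence length {len(sequence)} != locus length {gene_model.locus_length}"
        )
    cpg_map = map_cpg_sites(sequence)
    islands = detect_cpg_islands(sequence, island_params)
    shores: list[ShoreRegion] = []
    regions: list[AssayRegion] = []
    for isl in islands:
        up, down = delineate_shores(isl, gene_model.locus_length, neighbors=islands)
        shores.extend([up, down])
        regions.extend(
            select_assay_regions(
                cpg_map, isl, [up, down],
                min_cpgs=min_cpgs, max_span_bp=max_span_bp,
                density_ratio_max=density_ratio_max,
            )
        )
    return GeneLandscape(gene_model, cpg_map, islands, shores, regions)


def landscape_summary(landscape: GeneLandscape) -> dict:
    """JSON-ready summary with both locus-offset and TSS-relative coordinates."""
    gm = landscape.gene_model

    def both(off: int) -> dict:
        # End coordinates are exclusive; display the last included base.
        return {"offset": off, "display": to_display_coordinates(off, gm)}

    def interval(s: int, e: int) -> dict:
        return {"start": both(s), "end_inclusive": both(e - 1), "length": e - s}

    return {
        "gene_id": gm.gene_id,
        "chrom": gm.chrom,
        "strand": gm.strand,
        "locus_length": gm.locus_length,
        "n_cpg": len(landscape.cpg_map.positions),
        "islands": [
            {**interval(i.start, i.end),
             "gc_fraction": round(i.gc_fraction, 4),
             "obs_exp_cpg": round(i.obs_exp_cpg, 4),
             "cpg_count": i.cpg_count}
            for i in landscape.islands
        ],
        "shores": [
            {**interval(s.start, s.end), "side": s.side, "clipped": s.clipped}
            for s in landscape.shores
        ],
        "assay_regions": [
            {**interval(r.start, r.end), "label": r.label,
             "cpg_count": r.cpg_count, "cpg_density_per_100bp": round(r.cpg_density, 3)}
            for r in landscape.assay_regions
        ],
    }


def write_landscape_json(landscape: GeneLandscape, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(landscape_summary(landscape), fh, indent=2)
        fh.write("\n")
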