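"""Reading gene models (BED12/GFF3), loci (FASTA) and tabular inputs.

Minus-strand genes are flipped onto the coding strand exactly once, at load:
the locus sequence is reverse-complemented and the gene model's coordinates
are mirrored into the flipped frame, so every downstream module sees the
displayed strand with transcription running left to right.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .bisulfite import Amplicon
from .landscape import GeneModel

__all__ = [
    "read_gene_models_bed",
    "read_gene_models_gff3",
    "read_fasta",
    "load_locus",
    "read_amplicons",
    "read_clones",
    "read_pyro_table",
    "read_cohort",
]

_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand", "thick_start",
    "thick_end", "item_rgb", "block_count", "block_sizes", "block_starts",
]


def read_gene_models_bed(
    path: str | Path, pad_upstream: int = 2000, pad_downstream: int = 2000
) -> list[GeneModel]:
    """Gene models from a BED12 file (one transcript per line)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=_BED12_COLS, dtype={"chrom": str, "name": str})
    models = []
    for _, r in df.iterrows():
        sizes = [int(x) for x in str(r.block_sizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(r.block_starts).rstrip(",").split(",")]
        exons = tuple(
            (int(r.start) + s, int(r.start) + s + sz)
            for s, sz in zip(starts, sizes)
        )
        tss = int(r.start) if r.strand == "+" else int(r.end) - 1
        models.append(
            GeneModel(
                gene_id=str(r["name"]), chrom=str(r.chrom), strand=str(r.strand),
                tss=tss, exons=exons,
                pad_upstream=pad_upstream, pad_downstream=pad_downstream,
            )
        )
    return models


def read_gene_models_gff3(
    path: str | Path, pad_upstream: int = 2000, pad_downstream: int = 2000
) -> list[GeneModel]:
    """Gene models from a GFF3 file: exon features grouped by Parent/gene."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type(("gene", "mRNA", "transcript")):
        exons = sorted(
            (f.start - 1, f.end)  # GFF3 is 1-based closed
            for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            continue
        tss = exons[0][0] if gene.strand == "+" else exons[-1][1] - 1
        models.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                tss=tss, exons=tuple(exons),
                pad_upstream=pad_upstream, pad_downstream=pad_downstream,
            )
        )
    return models


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def load_locus(fasta_path: str | Path, gene_model: GeneModel
               ) -> tuple[str, GeneModel]:
    """Locus sequence and gene model on the displayed (coding) strand.

    The FASTA record may be either the chromosome named ``gene_model.chrom``
    (the locus window is sliced out) or a pre-extracted window named after
    the gene.  Minus-strand genes are reverse-complemented and mirrored here.
    """
    seqs = read_fasta(fasta_path)
    if gene_model.chrom in seqs:
        chrom_seq = seqs[gene_model.chrom]
        seq = chrom_seq[gene_model.locus_start : gene_model.locus_end]
    elif gene_model.gene_id in seqs:
        seq = seqs[gene_model.gene_id]
        if len(seq) != gene_model.locus_length:
            raise ValueError(
                f"record {gene_model.gene_id!r} length {len(seq)} != locus "
                f"window {gene_model.locus_length}"
            )
    else:
        raise KeyError(
            f"FASTA contains neither {gene_model.chrom!r} nor "
            f"{gene_model.gene_id!r}"
        )
    if len(seq) != gene_model.locus_length:
        raise ValueError("locus window extends beyond the FASTA record")

    if gene_model.strand == "+":
        return seq, gene_model

    # Mirror into the flipped frame: new_offset = L - 1 - old_offset.
    L = gene_model.locus_length
    origin = gene_model.locus_start
    flipped_exons = tuple(
        sorted(
            (L - (e - origin), L - (s - origin))
            for s, e in gene_model.exons
        )
    )
    flipped = GeneModel(
        gene_id=gene_model.gene_id, chrom=gene_model.chrom, strand="-",
        tss=L - 1 - (gene_model.tss - origin),
        exons=flipped_exons,
        pad_upstream=gene_model.pad_downstream,
        pad_downstream=gene_model.pad_upstream,
    )
    # In the flipped frame the locus starts at 0, so undo the pad shift.
    flipped = GeneModel(
        gene_id=flipped.gene_id, chrom=flipped.chrom, strand="-",
        tss=flipped.tss, exons=flipped_exons,
        pad_upstream=flipped_exons[0][0],
        pad_downstream=L - flipped_exons[-1][1],
    )
    return reverse_complement(seq), flipped


def read_amplicons(path: str | Path) -> dict[str, Amplicon]:
    """Amplicon references from FASTA; CpG offsets found automatically."""
    return {
        name: Amplicon(id=name, ref_seq=seq)
        for name, seq in read_fasta(path).items()
    }


def read_clones(path: str | Path) -> list[tuple[str, str]]:
    return list(read_fasta(path).items())


def read_pyro_table(path: str | Path) -> pd.DataFrame:
    """Pyro results: subject_id, amplicon_id, cpg_index, percent_meth, rlu."""
    df = pd.read_csv(path)
    required = {"subject_id", "amplicon_id", "cpg_index", "percent_meth", "rlu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pyro table missing columns: {sorted(missing)}")
    return df


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Cohort table; requires subject_id and group columns."""
    df = pd.read_csv(path)
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df
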