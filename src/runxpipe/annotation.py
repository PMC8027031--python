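"""Toy gene-model annotation and center-based genomic-region assignment.

Coordinates are 1-based inclusive internally and in GFF-lite files; BED-like
peak intervals elsewhere in the package are 0-based half-open and converted
at the boundary.  A peak center is classified into one of eight classes with
the precedence promoter > 5'UTR > CDS > 1st intron > other introns > 3'UTR >
downstream > intergenic.  Promoter and downstream windows are strand-aware:
promoter = TSS -2000..+500 bp, downstream = 2000 bp past the 3' end.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

PROMOTER_UP = 2000
PROMOTER_DOWN = 500
DOWNSTREAM_LEN = 2000

REGION_PRECEDENCE = (
    "promoter",
    "five_prime_UTR",
    "CDS",
    "first_intron",
    "other_introns",
    "three_prime_UTR",
    "downstream",
)

Interval = tuple[int, int]  # 1-based inclusive


def _contains(intervals: list[Interval], pos: int) -> bool:
    return any(a <= pos <= b for a, b in intervals)


@dataclass
class GeneModel:
    """One gene: exon/UTR/CDS structure on a single chromosome."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[Interval]
    five_utr: list[Interval]
    three_utr: list[Interval]
    cds: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt[0] <= prev[1]:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """3' end of the transcript."""
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> list[Interval]:
        """Introns in transcription order (first = nearest the TSS)."""
        gaps = [(a[1] + 1, b[0] - 1) for a, b in zip(self.exons, self.exons[1:])]
        return gaps if self.strand == "+" else gaps[::-1]

    @property
    def promoter(self) -> Interval:
        if self.strand == "+":
            return (self.tss - PROMOTER_UP, self.tss + PROMOTER_DOWN)
        return (self.tss - PROMOTER_DOWN, self.tss + PROMOTER_UP)

    @property
    def downstream(self) -> Interval:
        if self.strand == "+":
            return (self.tes + 1, self.tes + DOWNSTREAM_LEN)
        return (self.tes - DOWNSTREAM_LEN, self.tes - 1)

    def region_of(self, pos: int) -> str | None:
        """Region class of a 1-based position within this gene's windows."""
        a, b = self.promoter
        if a <= pos <= b:
            return "promoter"
        if _contains(self.five_utr, pos):
            return "five_prime_UTR"
        if _contains(self.cds, pos):
            return "CDS"
        introns = self.introns
        if introns and introns[0][0] <= pos <= introns[0][1]:
            return "first_intron"
        if any(a <= pos <= b for a, b in introns[1:]):
            return "other_introns"
        if _contains(self.three_utr, pos):
            return "three_prime_UTR"
        a, b = self.downstream
        if a <= pos <= b:
            return "downstream"
        return None


@dataclass
class GenomeAnnotation:
    """A single-chromosome set of non-overlapping gene models."""

    genes: list[GeneModel]
    chrom: str = "chrS"
    chrom_length: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 and self.genes:
            self.chrom_length = max(g.end for g in self.genes) + 20_000
        self.genes = sorted(self.genes, key=lambda g: g.start)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def assign(self, pos: int) -> tuple[str, str | None]:
        """(region label, gene id) for a 1-based chromosome position.

        Across genes the label with the highest precedence wins; among genes
        offering the same label the nearest TSS wins, then the
        lexicographically smaller gene id.
        """
        if not 1 <= pos <= self.chrom_length:
            raise ValueError(f"position {pos} outside chromosome "
                             f"[1, {self.chrom_length}]")
        candidates = []
        for g in self.genes:
            label = g.region_of(pos)
            if label is not None:
                candidates.append((REGION_PRECEDENCE.index(label),
                                   abs(pos - g.tss), g.gene_id, label))
        if not candidates:
            return "intergenic", None
        prec, _, gene_id, label = min(candidates)
        return label, gene_id


def write_gff_lite(path: str | Path, annotation: GenomeAnnotation,
                   source: str = "runxpipe") -> None:
    """Write the annotation as a GFF-lite TSV (1-based inclusive)."""
    rows = []
    for g in annotation.genes:
        rows.append((annotation.chrom, source, "gene", g.start, g.end,
                     g.strand, g.gene_id))
        for kind, ivals in (("exon", g.exons), ("five_prime_UTR", g.five_utr),
                            ("CDS", g.cds), ("three_prime_UTR", g.three_utr)):
            for a, b in ivals:
                rows.append((annotation.chrom, source, kind, a, b,
                             g.strand, g.gene_id))
    pd.DataFrame(rows, columns=["seqid", "source", "type", "start", "end",
                                "strand", "gene_id"]
                 ).to_csv(path, sep="\t", index=False)


def read_gff_lite(path: str | Path) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t")
    required = {"seqid", "type", "start", "end", "strand", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"GFF-lite missing columns {required - set(df.columns)}")
    chroms = df["seqid"].unique()
    if len(chroms) != 1:
        raise ValueError("expected a single-chromosome annotation")
    genes = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        ivals = {k: [(int(r.start), int(r.end))
                     for r in grp[grp["type"] == k].itertuples()]
                 for k in ("gene", "exon", "five_prime_UTR", "CDS",
                           "three_prime_UTR")}
        (gs, ge), = ivals["gene"]
        genes.append(GeneModel(
            gene_id=str(gene_id), chrom=str(chroms[0]), start=gs, end=ge,
            strand=str(grp["strand"].iloc[0]), exons=ivals["exon"],
            five_utr=ivals["five_prime_UTR"], cds=ivals["CDS"],
            three_utr=ivals["three_prime_UTR"]))
    return GenomeAnnotation(genes=genes, chrom=str(chroms[0]))
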