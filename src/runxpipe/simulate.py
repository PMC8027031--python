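"""Synthetic pipeline inputs with known ground truth.

Each generator takes a :class:`~runxpipe.config.SimulationConfig` and a
fresh seeded RNG derived from it, so identical (config, seed) pairs give
bit-identical outputs and no global RNG state is touched.

What is emulated
----------------
* expression: gene x sample log2 intensities for WT and two mutants with a
  planted fraction of up/down genes shifted by ``effect_size_log2`` in the
  mutant conditions only, i.i.d. Gaussian noise on the log2 scale;
* annotation: a toy single chromosome of non-overlapping three-exon genes on
  alternating strands so every region class (promoter, UTRs, CDS, first and
  other introns, downstream) is realizable;
* peak calls: two ChIP/input pairs per genotype, negative-binomial counts
  around per-peak means scaled to the library size; promoter peaks of
  planted up-genes gain ``+peak_effect_log2`` (down-genes lose the same) in
  the mutant genotypes;
* mutations: a protein-coordinate catalog with a ``cluster_weight`` fraction
  of mutations placed within +-3 residues of the configured hotspot centers;
* survival: exponential event times with log-hazard linear in standardized
  expression, independent exponential censoring.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation
from .config import SimulationConfig
from .expression import ExpressionMatrix

__all__ = [
    "GroundTruth",
    "MutationCatalog",
    "PeakCallSet",
    "simulate_expression",
    "simulate_annotation",
    "simulate_peak_calls",
    "simulate_mutations",
    "simulate_survival",
]

CLUSTER_HALF_WIDTH = 3  # residues around a hotspot center
GENE_LENGTH = 6000
GENE_GAP = 10_000
PEAK_HALF_WIDTH = 200
PEAK_JITTER = 50


@dataclass
class GroundTruth:
    """Planted labels aligned one-to-one with the generated entities."""

    deg_labels: Optional[pd.DataFrame] = None      # gene x comparison, {up,down,null}
    peak_shift_labels: Optional[pd.Series] = None  # peak -> {increased,decreased,unchanged}
    peak_gene: Optional[pd.Series] = None          # peak -> promoter gene (or <NA>)
    true_mcr_intervals: Optional[list[tuple[int, int]]] = None
    true_hazard_log_ratio: Optional[float] = None

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        for name in ("deg_labels", "peak_shift_labels", "peak_gene",
                     "true_mcr_intervals", "true_hazard_log_ratio"):
            if getattr(other, name) is not None:
                setattr(self, name, getattr(other, name))
        return self


@dataclass
class MutationCatalog:
    """Protein-coordinate somatic mutations; recurrent events repeat."""

    protein_id: str
    protein_length: int
    mutations: pd.DataFrame  # position_aa, mutation_class, effect

    def __post_init__(self) -> None:
        pos = self.mutations["position_aa"]
        if len(pos) and not ((pos >= 1) & (pos <= self.protein_length)).all():
            bad = pos[(pos < 1) | (pos > self.protein_length)].tolist()
            raise ValueError(f"mutation positions outside protein: {bad}")

    def __len__(self) -> int:
        return len(self.mutations)


@dataclass
class PeakCallSet:
    """One sample's peak calls (0-based half-open intervals with counts)."""

    sample_id: str
    pair_id: str
    genotype: str
    library_size: int
    intervals: pd.DataFrame  # chrom, start, end, name, read_count

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise ValueError("malformed interval: start must be < end")
        if len(iv) and (iv["read_count"] < 0).any():
            raise ValueError("negative read counts")
        if self.library_size < int(iv["read_count"].sum()):
            raise ValueError("library_size smaller than summed counts")


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator (crc32 is stable across
    # processes, unlike the built-in str hash)
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(config.seed, key)))


def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, GroundTruth]:
    """Planted-DEG log2 expression matrix and its truth labels."""
    if config.n_genes < 10:
        raise ValueError("n_genes < 10 is too small for permutation nulls")
    rng = _rng(config, "expression")
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    samples = [f"{c}_{r + 1}" for c in config.conditions
               for r in range(config.n_reps)]
    conditions = pd.Series([c for c in config.conditions
                            for _ in range(config.n_reps)], index=samples)

    n_deg = int(round(config.deg_fraction * config.n_genes))
    chosen = rng.choice(config.n_genes, size=n_deg, replace=False)
    n_up = (n_deg + 1) // 2
    up_idx, down_idx = chosen[:n_up], chosen[n_up:]

    baseline = rng.normal(8.0, 1.5, size=config.n_genes)
    shift = np.zeros(config.n_genes)
    shift[up_idx] = config.effect_size_log2
    shift[down_idx] = -config.effect_size_log2

    is_mutant = (conditions != config.reference).to_numpy()
    mean = baseline[:, None] + np.where(is_mutant[None, :], shift[:, None], 0.0)
    values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)

    labels = np.full(config.n_genes, "null", dtype=object)
    if config.effect_size_log2 > 0:
        labels[up_idx] = "up"
        labels[down_idx] = "down"
    deg_labels = pd.DataFrame({cmp: labels for cmp in config.comparisons},
                              index=genes)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        conditions=conditions)
    return matrix, GroundTruth(deg_labels=deg_labels)


def _plus_layout() -> dict[str, list[tuple[int, int]]]:
    # offsets within a 6 kb gene body, plus strand, 0-based inclusive
    return {
        "exons": [(0, 599), (2600, 3099), (5100, 5999)],
        "five_utr": [(0, 199)],
        "cds": [(200, 599), (2600, 3099), (5100, 5399)],
        "three_utr": [(5400, 5999)],
    }


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Non-overlapping three-exon gene models on alternating strands."""
    genes = []
    layout = _plus_layout()
    for i in range(config.n_genes):
        start = GENE_GAP + i * (GENE_LENGTH + GENE_GAP) + 1  # 1-based
        strand = "+" if i % 2 == 0 else "-"

        def place(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
            if strand == "+":
                return [(start + a, start + b) for a, b in ivals]
            return sorted((start + (GENE_LENGTH - 1 - b),
                           start + (GENE_LENGTH - 1 - a)) for a, b in ivals)

        genes.append(GeneModel(
            gene_id=f"g{i:05d}", chrom="chrS", start=start,
            end=start + GENE_LENGTH - 1, strand=strand,
            exons=place(layout["exons"]), five_utr=place(layout["five_utr"]),
            cds=place(layout["cds"]), three_utr=place(layout["three_utr"])))
    length = GENE_GAP + config.n_genes * (GENE_LENGTH + GENE_GAP)
    return GenomeAnnotation(genes=genes, chrom="chrS", chrom_length=length)


def simulate_peak_calls(config: SimulationConfig,
                        annotation: GenomeAnnotation,
                        truth: GroundTruth) -> list[PeakCallSet]:
    """Two jittered peak-call sets per genotype with planted binding shifts.

    One peak is placed in each gene's promoter (up to ``n_peaks``); any
    remainder is placed intergenically.  Negative-binomial counts are drawn
    around per-peak means that sum to ``library_size``; in mutant genotypes
    the promoter peaks of planted up/down genes are scaled by
    ``2**(+-peak_effect_log2)``.
    """
    if truth.deg_labels is None or len(truth.deg_labels) != len(annotation.genes):
        raise ValueError("truth labels do not match the annotation gene count")
    rng = _rng(config, "peaks")
    labels = truth.deg_labels.iloc[:, 0]  # planted set is shared across mutants

    names, starts, ends, shift, peak_gene = [], [], [], [], []
    n_gene_peaks = min(config.n_peaks, len(annotation.genes))
    for g in annotation.genes[:n_gene_peaks]:
        off = int(rng.integers(-1500, 301))  # inside the promoter window
        center1 = g.tss + off if g.strand == "+" else g.tss - off
        start0 = center1 - 1 - PEAK_HALF_WIDTH
        names.append(f"peak_{len(names):05d}")
        starts.append(start0)
        ends.append(start0 + 2 * PEAK_HALF_WIDTH)
        lbl = labels.loc[g.gene_id]
        shift.append("increased" if lbl == "up"
                     else "decreased" if lbl == "down" else "unchanged")
        peak_gene.append(g.gene_id)
    for _ in range(config.n_peaks - n_gene_peaks):
        # middle of a random inter-gene gap, clear of promoter/downstream
        i = int(rng.integers(0, len(annotation.genes) - 1))
        gap_lo = annotation.genes[i].end + 2500
        gap_hi = annotation.genes[i + 1].start - 2500
        center1 = int(rng.integers(gap_lo, gap_hi))
        names.append(f"peak_{len(names):05d}")
        starts.append(center1 - 1 - PEAK_HALF_WIDTH)
        ends.append(center1 - 1 + PEAK_HALF_WIDTH)
        shift.append("unchanged")
        peak_gene.append(pd.NA)

    shift = pd.Series(shift, index=names, name="peak_shift")
    base_mean = rng.gamma(shape=2.0, scale=1.0, size=config.n_peaks)
    base_mean *= config.library_size / base_mean.sum()

    mult = {"increased": 2.0 ** config.peak_effect_log2,
            "decreased": 2.0 ** -config.peak_effect_log2,
            "unchanged": 1.0}
    shift_mult = shift.map(mult).to_numpy()

    call_sets = []
    disp = config.nb_dispersion
    for genotype in config.conditions:
        for rep in (1, 2):
            mean = base_mean * (shift_mult if genotype != config.reference
                                else 1.0)
            r = 1.0 / disp
            counts = rng.negative_binomial(r, r / (r + mean))
            js, je = rng.integers(-PEAK_JITTER, PEAK_JITTER + 1,
                                  size=(2, config.n_peaks))
            s = np.maximum(np.array(starts) + js, 0)
            e = np.maximum(np.array(ends) + je, s + 1)
            df = pd.DataFrame({"chrom": annotation.chrom, "start": s,
                               "end": e, "name": names,
                               "read_count": counts})
            lib = max(int(round(mean.sum())), int(counts.sum()))
            call_sets.append(PeakCallSet(
                sample_id=f"{genotype}_chip_{rep}",
                pair_id=f"{genotype}_{rep}", genotype=genotype,
                library_size=lib, intervals=df))
    truth.peak_shift_labels = shift
    truth.peak_gene = pd.Series(peak_gene, index=names, name="gene_id")
    return call_sets


def simulate_mutations(config: SimulationConfig
                       ) -> tuple[MutationCatalog, GroundTruth]:
    """Mutation catalog with hotspots around the configured centers."""
    rng = _rng(config, "mutations")
    L, n = config.protein_length, config.n_mutations
    n_clustered = int(round(config.cluster_weight * n))
    pos = np.empty(n, dtype=int)
    if n_clustered:
        centers = rng.choice(np.asarray(config.cluster_centers), size=n_clustered)
        offs = rng.integers(-CLUSTER_HALF_WIDTH, CLUSTER_HALF_WIDTH + 1,
                            size=n_clustered)
        pos[:n_clustered] = np.clip(centers + offs, 1, L)
    pos[n_clustered:] = rng.integers(1, L + 1, size=n - n_clustered)

    is_snv = rng.random(n) < 0.8
    effect = np.where(is_snv,
                      np.where(rng.random(n) < 0.75,
                               "non_synonymous", "synonymous"),
                      "non_synonymous")
    catalog = MutationCatalog(
        protein_id="RUNX3", protein_length=L,
        mutations=pd.DataFrame({
            "position_aa": pos,
            "mutation_class": np.where(is_snv, "SNV", "INDEL"),
            "effect": effect}))
    intervals = [(max(1, c - CLUSTER_HALF_WIDTH),
                  min(L, c + CLUSTER_HALF_WIDTH))
                 for c in config.cluster_centers] if n_clustered else []
    return catalog, GroundTruth(true_mcr_intervals=intervals)


def simulate_survival(config: SimulationConfig
                      ) -> tuple[pd.DataFrame, GroundTruth]:
    """Exponential survival with log-hazard linear in expression.

    Returns a table (patient_id, time, event, expression); the hazard of
    patient i is ``baseline_hazard * exp(hazard_log_ratio * z_i)`` with z
    the standardized log2 expression, censoring independent exponential at
    ``censor_rate`` (0 disables censoring).
    """
    rng = _rng(config, "survival")
    n = config.n_patients
    expr = rng.normal(8.0, 1.0, size=n)
    z = (expr - expr.mean()) / expr.std()
    lam = config.baseline_hazard * np.exp(config.hazard_log_ratio * z)
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    table = pd.DataFrame({
        "patient_id": [f"p{i:04d}" for i in range(n)],
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
        "expression": expr})
    return table, GroundTruth(true_hazard_log_ratio=config.hazard_log_ratio)
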