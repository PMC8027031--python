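"""Consensus-peak construction and peak x expression integration.

Per-sample peak calls (one ChIP/input pair each) are filtered at the
mapped-read cutoff (> 20 reads), merged into consensus peaks supported by at
least ``min_support`` distinct pairs, quantified as log2-CPM, compared
between genotypes as the mean difference of log2-CPM, assigned to genomic
regions by their center coordinate, and finally partitioned by the DEG class
of the assigned gene to compare binding-change distributions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeAnnotation
from .simulate import PeakCallSet

__all__ = [
    "ConsensusPeakTable",
    "RegionComparison",
    "filter_low_count",
    "build_consensus",
    "cpm_log2",
    "peak_log2fc",
    "annotate_peaks",
    "density_profile",
    "integrate_with_degs",
]

READ_COUNT_MIN = 20  # peaks with <= this many mapped reads are dropped


@dataclass
class ConsensusPeakTable:
    """Consensus intervals with per-sample quantification.

    ``peaks``: peak_id-indexed (chrom, start, end, support) plus, once
    assigned, region_label and assigned_gene columns.  ``counts``/``cpm``/
    ``log2_cpm``: peak x sample matrices.  ``log2_fc``: peak x comparison.
    ``samples``: sample_id-indexed metadata (pair_id, genotype,
    library_size).
    """

    peaks: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame
    cpm: Optional[pd.DataFrame] = None
    log2_cpm: Optional[pd.DataFrame] = None
    log2_fc: Optional[pd.DataFrame] = None

    def __len__(self) -> int:
        return len(self.peaks)


def filter_low_count(peaks: PeakCallSet,
                     min_reads: int = READ_COUNT_MIN) -> PeakCallSet:
    """Retain exactly the intervals with read_count > ``min_reads``."""
    kept = peaks.intervals[peaks.intervals["read_count"] > min_reads]
    return PeakCallSet(sample_id=peaks.sample_id, pair_id=peaks.pair_id,
                       genotype=peaks.genotype,
                       library_size=peaks.library_size,
                       intervals=kept.reset_index(drop=True))


def build_consensus(call_sets: Sequence[PeakCallSet],
                    min_support: int = 2) -> ConsensusPeakTable:
    """Union-merge intervals into consensus peaks with pair support.

    Intervals from all samples that overlap by >= 1 bp (transitively) form a
    component; a component detected in >= ``min_support`` distinct
    ChIP/input pairs becomes a consensus peak spanning the union of its
    member intervals.  Per-sample counts are the sums of each sample's
    member interval counts.  Chromosomes are handled independently.
    """
    if len(call_sets) < min_support:
        raise ValueError("fewer call sets than min_support")
    frames = []
    for cs in call_sets:
        df = cs.intervals[["chrom", "start", "end", "read_count"]].copy()
        df["pair_id"] = cs.pair_id
        df["sample_id"] = cs.sample_id
        frames.append(df)
    allp = pd.concat(frames, ignore_index=True)

    sample_ids = [cs.sample_id for cs in call_sets]
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    peak_rows, count_rows = [], []
    for chrom, grp in allp.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        pairs = grp["pair_id"].to_numpy()
        samples_arr = grp["sample_id"].to_numpy()
        cnts = grp["read_count"].to_numpy()

        def flush(lo: int, hi: int, cs: int, ce: int) -> None:
            support = len(set(pairs[lo:hi]))
            if support >= min_support:
                peak_rows.append((chrom, cs, ce, support))
                row = np.zeros(len(sample_ids), dtype=np.int64)
                for s, c in zip(samples_arr[lo:hi], cnts[lo:hi]):
                    row[sample_pos[s]] += c
                count_rows.append(row)

        lo = 0
        cur_start = cur_end = None
        for i in range(len(grp)):
            if cur_end is None or starts[i] >= cur_end:  # half-open: no overlap
                if cur_end is not None:
                    flush(lo, i, cur_start, cur_end)
                lo, cur_start, cur_end = i, starts[i], ends[i]
            else:
                cur_end = max(cur_end, ends[i])
        if cur_end is not None:
            flush(lo, len(grp), cur_start, cur_end)

    peak_ids = [f"cons_{i:05d}" for i in range(len(peak_rows))]
    peaks = pd.DataFrame(peak_rows,
                         columns=["chrom", "start", "end", "support"],
                         index=pd.Index(peak_ids, name="peak_id"))
    counts = pd.DataFrame(np.array(count_rows, dtype=np.int64).reshape(
        len(peak_rows), len(sample_ids)),
        index=peaks.index, columns=sample_ids)
    samples = pd.DataFrame(
        {"pair_id": [cs.pair_id for cs in call_sets],
         "genotype": [cs.genotype for cs in call_sets],
         "library_size": [cs.library_size for cs in call_sets]},
        index=pd.Index(sample_ids, name="sample_id"))
    return ConsensusPeakTable(peaks=peaks, counts=counts, samples=samples)


def cpm_log2(table: ConsensusPeakTable) -> ConsensusPeakTable:
    """Populate cpm = count / library_size * 1e6 and log2_cpm = log2(cpm+1)."""
    lib = table.samples["library_size"].astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be > 0")
    table.cpm = table.counts / lib * 1e6
    table.log2_cpm = np.log2(table.cpm + 1.0)
    return table


def peak_log2fc(table: ConsensusPeakTable, mutant: str,
                reference: str = "WT", on: str = "log2_cpm") -> pd.Series:
    """Mean difference of log2 intensities, mutant minus reference.

    ``on='log2_cpm'`` (default) uses library-normalized log2-CPM;
    ``on='log2_count'`` uses raw log2(count + 1).
    """
    for g in (mutant, reference):
        if g not in set(table.samples["genotype"]):
            raise ValueError(f"genotype {g!r} absent from the sample sheet")
    if on == "log2_cpm":
        if table.log2_cpm is None:
            cpm_log2(table)
        mat = table.log2_cpm
    elif on == "log2_count":
        mat = np.log2(table.counts + 1.0)
    else:
        raise ValueError("on must be 'log2_cpm' or 'log2_count'")
    mut_cols = table.samples.index[table.samples["genotype"] == mutant]
    ref_cols = table.samples.index[table.samples["genotype"] == reference]
    lfc = mat[mut_cols].mean(axis=1) - mat[ref_cols].mean(axis=1)
    lfc.name = f"{mutant}_vs_{reference}"
    if table.log2_fc is None:
        table.log2_fc = pd.DataFrame(index=table.peaks.index)
    table.log2_fc[lfc.name] = lfc
    return lfc


def peak_center(start: int, end: int) -> int:
    """1-based center of a 0-based half-open interval."""
    return (start + end) // 2 + 1


def annotate_peaks(table: ConsensusPeakTable,
                   annotation: GenomeAnnotation) -> ConsensusPeakTable:
    """Assign each peak's center to a region class and a gene."""
    labels, genes = [], []
    for row in table.peaks.itertuples():
        label, gene = annotation.assign(peak_center(row.start, row.end))
        labels.append(label)
        genes.append(gene)
    table.peaks["region_label"] = labels
    table.peaks["assigned_gene"] = genes
    return table


def density_profile(coverage: np.ndarray, library_size: int,
                    half_window: int = 2000, bin_size: int = 50) -> np.ndarray:
    """Binned reads-per-million density around a peak center.

    ``coverage`` holds per-base read coverage over the +-half_window region
    (length 2*half_window, zero-filled past chromosome edges); each of the
    2*half_window/bin_size bins is the mean coverage in its window scaled to
    reads per million by the library size.
    """
    if (2 * half_window) % bin_size:
        raise ValueError("bin size must divide the window")
    coverage = np.asarray(coverage, dtype=float)
    if coverage.shape != (2 * half_window,):
        raise ValueError(f"coverage must have length {2 * half_window}")
    return coverage.reshape(-1, bin_size).mean(axis=1) * 1e6 / library_size


@dataclass
class RegionComparison:
    """Binding-change distributions per DEG class within one region."""

    region: str
    comparison: str
    class_values: dict[str, np.ndarray]
    class_means: dict[str, float]
    anova_f: Optional[float]
    anova_p: Optional[float]
    tukey: Optional[pd.DataFrame]
    ecdf: dict[str, tuple[np.ndarray, np.ndarray]]
    deg_increased_binding: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def _ecdf(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(x)
    return xs, np.arange(1, len(xs) + 1) / len(xs)


def integrate_with_degs(table: ConsensusPeakTable, degs: pd.DataFrame,
                        comparison: str, region: str = "promoter",
                        binding_lfc_threshold: float = 0.0
                        ) -> RegionComparison:
    """Partition a region's peaks by the DEG class of their assigned gene.

    ``degs`` is a gene-indexed table with a ``call`` column (up/down/
    non_deg); peaks whose gene is absent count as non_deg.  Reports the
    per-class log2-fold-change samples and ECDFs, one-way ANOVA across the
    classes with Tukey HSD pairwise comparisons, and the intersection list
    of genes that are DEGs AND have a promoter peak with log2FC above
    ``binding_lfc_threshold``.
    """
    if "region_label" not in table.peaks.columns:
        raise ValueError("peaks must be annotated before integration")
    if table.log2_fc is None or comparison not in table.log2_fc.columns:
        raise ValueError(f"log2 fold-changes for {comparison!r} not computed")
    calls = degs["call"] if "call" in degs.columns else pd.Series(dtype=object)
    peak_class = table.peaks["assigned_gene"].map(calls).fillna("non_deg")

    sel = table.peaks["region_label"] == region
    lfc = table.log2_fc.loc[sel, comparison]
    cls = peak_class[sel]
    class_values = {c: lfc[cls == c].to_numpy()
                    for c in ("up", "down", "non_deg")}
    class_means = {c: float(v.mean()) if len(v) else float("nan")
                   for c, v in class_values.items()}
    ecdf = {c: _ecdf(v) for c, v in class_values.items() if len(v)}

    msgs = []
    groups = {c: v for c, v in class_values.items() if len(v) >= 2}
    anova_f = anova_p = None
    tukey = None
    if len(groups) >= 2:
        small = sorted(set(class_values) - set(groups))
        if small:
            msgs.append(f"classes with <2 peaks skipped in ANOVA: {small}")
        anova_f, anova_p = map(float, stats.f_oneway(*groups.values()))
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        data = np.concatenate(list(groups.values()))
        lab = np.concatenate([[c] * len(v) for c, v in groups.items()])
        res = pairwise_tukeyhsd(data, lab)
        tukey = pd.DataFrame(res.summary().data[1:],
                             columns=res.summary().data[0])
    else:
        msgs.append("fewer than two classes with >=2 peaks; ANOVA skipped")
        warnings.warn(msgs[-1])

    promoter = table.peaks["region_label"] == "promoter"
    binding = pd.DataFrame({
        "gene_id": table.peaks.loc[promoter, "assigned_gene"],
        "log2_fc": table.log2_fc.loc[promoter, comparison]})
    binding = (binding.dropna()
               .groupby("gene_id")["log2_fc"].max()
               .rename("max_promoter_log2fc").reset_index())
    binding["call"] = binding["gene_id"].map(calls).fillna("non_deg")
    increased = binding[(binding["call"].isin(["up", "down"]))
                        & (binding["max_promoter_log2fc"]
                           > binding_lfc_threshold)]
    return RegionComparison(
        region=region, comparison=comparison, class_values=class_values,
        class_means=class_means, anova_f=anova_f, anova_p=anova_p,
        tukey=tukey, ecdf=ecdf,
        deg_increased_binding=increased.reset_index(drop=True),
        warnings=msgs)
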