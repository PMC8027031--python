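# Methods

This package re-implements, as tested library code, four downstream
computations used to characterize how hypoxia-induced methylation of the
RUNX3 transcription factor (at Runt-domain lysines K129 and K171) rewires
its target-gene program in gastric cancer: an integrative
differential-expression statistic, ChIP-seq consensus-peak integration
with expression classes, a scan-statistic mutation-cluster caller on
protein coordinates, and a quartile-stratified survival comparison.  All
four run on synthetic inputs with planted ground truth, so every claim the
test suite makes is a claim about the statistical machinery, not about any
cohort.

## Integrative differential expression

For each two-group comparison (a Runt-domain mutant versus wild type) and
each gene we compute

* a pooled-variance Student t statistic `t = (x̄_A − x̄_B) / (s_p √(1/n_A + 1/n_B))`
  and its two-sided parametric p at `n_A + n_B − 2` df;
* the log2-median-ratio `LMR = median(A) − median(B)` on the
  quantile-normalized log2 scale.

Because two or three replicates per condition cannot support per-gene
nulls, empirical nulls are built by permuting the sample labels of the two
compared groups jointly and pooling the permuted t and LMR values across
all genes.  When the design admits fewer distinct label splits than
requested — always at this scale — all distinct non-identity splits are
enumerated instead (2 splits for the 2v2 design, 9 for 3v3; a split and
its mirror image are the same partition).  Two-sided empirical p-values
use the `+1/(N+1)` correction so they are never zero, and the two p's are
combined with Stouffer's method, `Z = (z_t + z_LMR)/√2` with
`z = Φ⁻¹(1 − p)`; an exactly-uninformative p of 1 contributes `z = 0`
rather than `−∞`.  A gene is called up (down) when all of
`overall p < 0.01`, `t-test p < 0.1` and `|LMR| > 0.406` hold with
`LMR > 0` (`< 0`).  The 0.406 cutoff corresponds to a 1.33-fold linear
change (`2^0.406 = 1.33` to two decimals); an alternative cutoff derived
from the permutation null — the mean of the absolute 1st and 99th LMR
percentiles — is available (`lmr_cutoff="derived"`).

**Calibration caveat (measured, not assumed).**  The marginal empirical
p-values calibrate: on zero-effect simulations the fraction of genes with
`p_t_emp < 0.01` or `p_lmr_emp < 0.01` sits at ≈0.01.  The *combined*
statistic does not: t and LMR are computed from the same handful of
samples and are strongly dependent, while Stouffer's combination assumes
independence, so the fraction of null genes with `overall p < 0.01` is
≈0.03–0.04 (2000 genes, triplicate design; `06_calibration_studies.py`
reproduces this).  This liberal bias is a property of the combination
rule itself; we report it rather than correct it, because the three-way
conjunction with the t-test p and the LMR magnitude is what defines a
call, and the planted-recovery study below shows the conjunction's
realized FDR stays near 0.1 under the standard conditions.

**Power and the replicate count.**  At the duplicate design the pooled t
test has only 2 df; its power at `t p < 0.1` for a 1.0-log2 effect with
0.25 noise SD is ≈0.8, which caps end-to-end sensitivity near 0.8 (the
analysis drivers print ≈0.77–0.79).  The calibration and recovery studies
therefore use triplicates (power ≈0.95, realized sensitivity ≈0.94–0.95,
FDR ≈0.06–0.13), while the generator default stays at two replicates —
the design of the study being emulated.

Degenerate genes with zero within-group variance in both groups get
`t = 0` when the means agree and a finite cap (±1e6, clipped into the
pooled null) otherwise.  Medians of even-sized groups are midpoints of
the two central order statistics.

## ChIP-seq consensus peaks and integration

Inputs are per-pair (ChIP/input) peak-call tables: BED-like 0-based
half-open intervals with mapped-read counts, two pairs per genotype.
Processing:

1. drop intervals with ≤ 20 mapped reads;
2. merge intervals that overlap by ≥ 1 bp (transitively) across samples;
   a merged component detected in ≥ 2 distinct pairs (of 6) becomes a
   consensus peak spanning the union of its members, and per-sample counts
   are the sums of that sample's member-interval counts.  The sweep-merge
   is checked exactly against a quadratic per-base union-find oracle;
   touching-but-not-overlapping intervals do not merge;
3. `CPM = count / library_size × 10⁶`, `log2-CPM = log2(CPM + 1)`; the
   per-comparison binding change is the mean difference of log2-CPM
   (mutant minus WT; computing on raw `log2(count+1)` is a switch);
4. each peak is assigned by its center base to one region with precedence
   promoter > 5′UTR > CDS > 1st intron > other introns > 3′UTR >
   downstream > intergenic.  The promoter window is TSS −2000..+500 bp and
   the downstream window 2000 bp past the 3′ end, both strand-aware; the
   first intron is the intron nearest the TSS in transcription order.
   Among genes offering the same class the nearest TSS wins, then the
   lexicographically smaller gene id;
5. peaks in a region are partitioned by the DEG class of their assigned
   gene (genes absent from the DEG table count as non-DEG) and the class
   log2-fold-change distributions are compared by one-way ANOVA with
   Tukey HSD, with per-class ECDFs; the intersection list reports DEGs
   whose best promoter peak changed by more than a threshold (default
   > 0).

Binned read-density profiles around peak centers (±2 kb, 50-bp bins, 80
bins, reads-per-million scaling) are provided for density-heatmap style
summaries.

## Mutation cluster regions

On a protein of length L (default 415, the RUNX3 coordinate system), the
cluster score of residue i is `s_i = m_{i−1} + m_i + m_{i+1}` — the
mutation counts at the residue and its two immediate neighbors, truncated
at the termini (a five-residue window is an option).  SNVs (synonymous or
not) and INDELs all count; recurrent events count multiply in scores but
once toward the mutated-residue criterion.  Filters (`nonsyn_only`,
`include_indels`) support the non-synonymous-only reading.

Significance: the catalog's maximum score is compared with the maximum
obtained when the same number of mutations is placed uniformly at random
over the protein (`p = (1 + #{null ≥ obs}) / (1 + n_perm)`); the
estimate is validated against exact enumeration on a length-10 toy.
Candidate regions are maximal runs of residues with `s_i ≥ 1`, which
guarantees candidates are separated by ≥ 3 mutation-free residues; a
candidate is a mutation cluster region (MCR) iff its maximum score is
≥ 3, it contains ≥ 5 distinct mutated residues, and the catalog-level
permutation p is < 0.05.

## Survival

Cohort preprocessing keeps genes with FPKM > 1 in strictly more than 50%
of samples, transforms to `log2(FPKM+1)` and quantile-normalizes.
Patients are ranked by expression; exactly ⌊n/4⌋ land in each of the
high/low tails, ties resolved deterministically by patient id (flagged
with a warning when a tie actually spans a boundary).

The Gehan–Breslow–Wilcoxon test is the weighted log-rank with `w_j = n_j`
(the number at risk) at each distinct event time:
`χ² = [Σ w_j (d_1j − E_j)]² / Σ w_j² V_j` with the hypergeometric
`E_j = d_j n_1j / n_j` and
`V_j = d_j (n_1j/n_j)(1 − n_1j/n_j)(n_j − d_j)/(n_j − 1)` (0 when
`n_j = 1`), referred to χ²₁ (two-sided).  Forcing `w_j = 1` reproduces
the standard log-rank to 1e-8 against an independent reference
implementation.  Kaplan–Meier curves come from the product-limit
estimator.

## The synthetic-data generator

What it emulates, and the standard conditions:

* **expression** — gene × sample log2 intensities, baseline N(8, 1.5²),
  i.i.d. Gaussian noise on the log2 scale (default SD 0.25); a planted
  fraction (default 10%, half up / half down) shifted by ±1.0 log2 in the
  mutant conditions only.  Three conditions × 2 replicates by default.
* **annotation** — one toy chromosome of non-overlapping 6-kb three-exon
  genes (5′UTR/CDS/introns/3′UTR all realizable, first and other introns
  distinct) separated by 10-kb gaps, alternating strands.
* **peak calls** — one promoter peak per gene (extras intergenic), widths
  ≈400 bp with ±50 bp per-sample jitter; negative-binomial counts
  (dispersion 0.05) around per-peak Gamma means scaled to the library
  size (default 10⁶); promoter peaks of planted up-genes gain
  +1.0 log2 (down-genes lose the same) in mutant genotypes.  Recorded
  library sizes never fall below the summed counts.
* **mutations** — default 80 events, half placed within ±3 aa of the
  hotspot centers 129 and 171 (a realistic density for a pan-cancer
  catalog of a 415-aa tumor suppressor with two hotspots), the rest
  uniform; 80% SNV (75% of those non-synonymous), INDELs all
  non-synonymous.
* **survival** — default 400 patients; exponential event times with
  log-hazard linear in standardized expression (default slope −0.5,
  baseline hazard 0.1/time-unit) and independent exponential censoring
  (default rate 0.05; 0 disables).  The cohort size is a generator
  parameter because the power properties quoted above are stated at
  n = 400.

Not emulated: probe-level microarray structure, read-level sequencing
artifacts, copy-number or purity effects, correlated genes, tied event
times from coarse follow-up grids.  Passing tests therefore demonstrate
the correctness and calibration of the statistics under their own
assumptions, not robustness to those real-data features.

All generators draw from independent, reproducibly derived RNG streams of
a single seed; identical (config, seed) gives bit-identical outputs and
no global RNG state is touched.

## Standard study sizes

The repeated-simulation studies (`runxpipe.experiments`, driven by
`analysis/06_calibration_studies.py` and `scripts/acceptance.py`) use:
2000 genes (triplicate design, exhaustive 9-split nulls) for DEG
calibration and recovery; 100 random ≤10-kb instances for the consensus
oracle and 100 random catalogs for the score oracle; 200 replicates for
hotspot recovery (both hotspots must be recovered) and 500
uniform-catalog replicates for the MCR null rate; 500 replicates at
n = 200 for the GBW type-I error and 50 random tables for the log-rank
reduction; 100 replicates of the full 150-gene pipeline for the
promoter-direction study.

## Known limitations

* The combined DEG statistic is liberal under the null (see above); the
  package reports the measured tail rather than recalibrating it.
* The consensus rule merges to the union interval; no re-centering or
  trimming is attempted, so very ragged pile-ups can yield wide peaks.
* The MCR permutation null is catalog-level (on the maximum score), so a
  single dominant hotspot can carry a weaker secondary run past the
  p-value gate; the score and residue-count criteria still apply
  per region.
* Quartile tie-breaking by patient id is deterministic but arbitrary
  within a tie; with heavily discretized expression the two tails can
  differ only by id order.
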