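# runxpipe

Downstream statistics for a study of hypoxia-induced RUNX3 methylation in
gastric cancer, rebuilt as a tested, reusable Python package.  RUNX3 is a
tumor-suppressor transcription factor; methylation of two Runt-domain
lysines (K129, K171) under hypoxia changes its promoter binding and its
target-gene program.  The package implements the four bespoke
computations such a study needs downstream of standard read processing:

* **Integrative differential expression** — per-gene pooled-variance
  Student t and log2-median-ratio (LMR), genome-wide permutation nulls,
  Stouffer combination of the two empirical p-values, and the
  three-criterion call (overall p < 0.01, t-test p < 0.1,
  |LMR| > 0.406 ≙ 1.33-fold).
* **ChIP-seq consensus-peak integration** — read filter (> 20 mapped
  reads), union-merge consensus over ≥ 2 of 6 ChIP/input pairs, log2-CPM
  quantification, mean-difference fold-changes, center-based assignment
  to promoter/UTR/CDS/intron/downstream regions, and comparison of
  binding changes across DEG classes (one-way ANOVA + Tukey HSD).
* **Mutation cluster regions (MCRs)** — per-residue scan score
  `s_i = m_{i−1} + m_i + m_{i+1}` on protein coordinates, permutation
  test of the maximum score, and region calling (max score ≥ 3, ≥ 5
  mutated residues, p < 0.05).
* **Quartile-stratified survival** — expressed-gene filter
  (FPKM > 1 in > 50% of samples, log2(FPKM+1), quantile normalization),
  top/bottom-25% groups, Kaplan–Meier curves, and a from-scratch
  Gehan–Breslow–Wilcoxon weighted log-rank test
  (`w_j = n_j`; `w_j = 1` recovers the standard log-rank).

A synthetic-data generator (`runxpipe.simulate`) produces every input
with planted ground truth — planted up/down genes, shifted promoter
peaks, mutation hotspots at residues 129/171, an expression-linked hazard
— so each stage is testable end to end without downloading any cohort.
The model details, default parameters, and measured calibration
properties are in [docs/methods.md](docs/methods.md).

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated
data (1000 genes, 3 conditions × 2 replicates, 1000 peaks, 80 mutations,
400 patients; seed fixed in each script):

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_chip_integration.py
python analysis/04_mutation_clusters.py
python analysis/05_survival.py
python analysis/06_calibration_studies.py
```

which prints, stage by stage:

```
K129R_vs_WT: 52 up / 53 down of 1000 genes (sensitivity 0.770, FDR 0.267; derived LMR cutoff 0.586)
K171R_vs_WT: 46 up / 45 down of 1000 genes (sensitivity 0.790, FDR 0.132; derived LMR cutoff 0.603)
K129R_vs_WT: promoter log2FC means up=0.759 non_deg=-0.056 down=-0.833 (ANOVA p=6.04e-71); 54 DEGs with increased promoter binding
max cluster score 15 (permutation p = 9.999e-05 over 10000 draws)
  MCR 123-133 aa: max score 15, 8 mutated residues
  MCR 167-175 aa: max score 11, 7 mutated residues
GBW chi2 = 41.4005, p = 1.24e-10; log-rank chi2 = 47.0245, p = 7.011e-12
```

Reading the numbers: with two replicates the t test has 2 degrees of
freedom, so sensitivity tops out near 0.8 (the triplicate studies in
`06_calibration_studies.py` reach ≈0.95 at FDR ≈0.1); the planted ±1-log2
promoter effects separate the up/non-DEG/down class means by about one
log2 unit each way; the two planted hotspots around residues 129 and 171
are recovered as MCRs; and the protective expression–hazard link
(log-hazard slope −0.5) produces a decisive survival split between the
top and bottom expression quartiles.

Each stage writes its tables under `results/` (per-gene DEG tables,
consensus-peak matrix, per-residue cluster scores, per-event-time GBW
table, KM curves).  The same stages are scriptable through the
`runx-integrate` CLI (`run`, `simulate`, `deg`, `chip-integrate`, `mcr`,
`survival`) with a single YAML config, and `runxpipe.pipeline.run_all`
executes them end to end with a JSON manifest (parameters, output hashes,
row counts); reruns under a fixed config are byte-identical.

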