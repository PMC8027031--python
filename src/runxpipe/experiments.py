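"""Repeated-simulation experiments over the pipeline stages.

Each function runs one self-contained computational experiment — a
calibration, recovery, oracle-equivalence or directionality study — on
synthetic data with known truth, and returns plain scalars.  The analysis
drivers and the acceptance script are thin wrappers around these.

Problem sizes here are the package's standard study conditions: 2000 genes
for DEG calibration/recovery (triplicate design), 100 random instances for
the interval and score oracles, 200 replicates for hotspot recovery, 500
for type-I-error rates, 100 for the binding-direction study.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .clusters import cluster_scores, detect_mcrs
from .config import SimulationConfig
from .expression import call_degs, permutation_null, quantile_normalize
from .peaks import (annotate_peaks, build_consensus, cpm_log2,
                    integrate_with_degs, peak_log2fc)
from .simulate import (MutationCatalog, PeakCallSet, simulate_annotation,
                       simulate_expression, simulate_mutations,
                       simulate_peak_calls, simulate_survival)
from .survival import gbw_test, quartile_groups

__all__ = [
    "deg_null_calibration",
    "deg_planted_recovery",
    "consensus_oracle_check",
    "cluster_score_oracle_check",
    "mcr_planted_recovery",
    "mcr_null_call_rate",
    "gbw_toy_example",
    "logrank_reduction_check",
    "gbw_type_i_error",
    "promoter_direction_study",
]


# --------------------------------------------------------------------------
# differential expression

def _deg_run(config: SimulationConfig, n_perm: int, seed: int):
    matrix, truth = simulate_expression(config)
    matrix = quantile_normalize(matrix)
    nulls = permutation_null(matrix, "K129R", "WT", n_perm=n_perm, seed=seed)
    res = call_degs(matrix, "K129R", "WT", nulls)
    return res, truth.deg_labels["K129R_vs_WT"]


def deg_null_calibration(n_genes: int = 2000, n_reps: int = 3,
                         n_perm: int = 500, seed: int = 0) -> dict:
    """Fraction of zero-effect genes with combined overall_p < 0.01.

    For a perfectly calibrated statistic this sits near 0.01; dependence
    between the combined t and LMR p-values inflates it.
    """
    cfg = SimulationConfig(n_genes=n_genes, n_reps=n_reps,
                           effect_size_log2=0.0, noise_sd=0.25, seed=seed)
    res, _ = _deg_run(cfg, n_perm, seed)
    return {"fraction_overall_p_lt_0.01": float((res["overall_p"] < 0.01).mean()),
            "fraction_p_t_emp_lt_0.01": float((res["p_t_emp"] < 0.01).mean()),
            "fraction_p_lmr_emp_lt_0.01": float((res["p_lmr_emp"] < 0.01).mean()),
            "n_genes": n_genes}


def deg_planted_recovery(n_genes: int = 2000, n_reps: int = 3,
                         effect: float = 1.0, sd: float = 0.25,
                         deg_fraction: float = 0.1, n_perm: int = 500,
                         seed: int = 0) -> dict:
    """Sensitivity and FDR of the three-criterion call on planted DEGs."""
    cfg = SimulationConfig(n_genes=n_genes, n_reps=n_reps,
                           effect_size_log2=effect, noise_sd=sd,
                           deg_fraction=deg_fraction, seed=seed)
    res, labels = _deg_run(cfg, n_perm, seed)
    called = res["call"] != "non_deg"
    true_deg = labels != "null"
    sensitivity = float(called[true_deg].mean())
    n_called = int(called.sum())
    fdr = float((called & ~true_deg).sum() / n_called) if n_called else 0.0
    return {"sensitivity": sensitivity, "fdr": fdr,
            "n_true": int(true_deg.sum()), "n_called": n_called,
            "n_genes": n_genes}


# --------------------------------------------------------------------------
# consensus-peak oracle

def _brute_force_consensus(call_sets, min_support):
    """Quadratic per-base union-find; the independent geometry oracle."""
    rows = []
    for cs in call_sets:
        for r in cs.intervals.itertuples():
            rows.append((r.chrom, int(r.start), int(r.end), cs.pair_id))
    parent = list(range(len(rows)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if a[0] == b[0] and set(range(a[1], a[2])) & set(range(b[1], b[2])):
                parent[find(i)] = find(j)
    comps: dict[int, list] = {}
    for i in range(len(rows)):
        comps.setdefault(find(i), []).append(rows[i])
    out = []
    for members in comps.values():
        pairs = {m[3] for m in members}
        if len(pairs) >= min_support:
            out.append((members[0][0], min(m[1] for m in members),
                        max(m[2] for m in members), len(pairs)))
    return sorted(out)


def consensus_oracle_check(n_instances: int = 100, seed: int = 0) -> dict:
    """Sweep-merge vs brute-force oracle on random <=10 kb instances."""
    rng = np.random.default_rng(seed)
    n_agree = 0
    for _ in range(n_instances):
        sets = []
        for p in range(int(rng.integers(2, 7))):
            n = int(rng.integers(2, 10))
            ivals = []
            for _ in range(n):
                s = int(rng.integers(0, 9500))
                ivals.append(("chr1", s, s + int(rng.integers(1, 500)),
                              f"iv{len(ivals)}", int(rng.integers(21, 300))))
            sets.append(PeakCallSet(
                sample_id=f"s{p}", pair_id=f"pair{p}", genotype="WT",
                library_size=10**6,
                intervals=pd.DataFrame(ivals, columns=[
                    "chrom", "start", "end", "name", "read_count"])))
        table = build_consensus(sets, min_support=2)
        got = sorted((r.chrom, int(r.start), int(r.end), int(r.support))
                     for r in table.peaks.itertuples())
        n_agree += got == _brute_force_consensus(sets, 2)
    return {"n_agree": n_agree, "n_instances": n_instances}


# --------------------------------------------------------------------------
# mutation clusters

def cluster_score_oracle_check(n_catalogs: int = 100, seed: int = 0) -> dict:
    """Window scores vs an O(L*M) per-residue recount on random catalogs."""
    rng = np.random.default_rng(seed)
    n_agree = 0
    for _ in range(n_catalogs):
        L = int(rng.integers(10, 400))
        m = int(rng.integers(0, 50))
        pos = rng.integers(1, L + 1, size=m)
        cat = MutationCatalog(
            protein_id="P", protein_length=L,
            mutations=pd.DataFrame({"position_aa": pos,
                                    "mutation_class": "SNV",
                                    "effect": "non_synonymous"}))
        brute = np.array([int(np.sum(np.abs(pos - i) <= 1))
                          for i in range(1, L + 1)])
        n_agree += np.array_equal(cluster_scores(cat), brute)
    return {"n_agree": n_agree, "n_catalogs": n_catalogs}


def mcr_planted_recovery(n_replicates: int = 200, n_perm: int = 500,
                         seed: int = 0) -> dict:
    """Fraction of replicates recovering BOTH planted hotspots as MCRs."""
    recovered = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + rep)
        cat, truth = simulate_mutations(cfg)
        res = detect_mcrs(cat, n_perm=n_perm, seed=seed + rep)
        hit = all(((res.mcrs["start_aa"] <= hi) &
                   (res.mcrs["end_aa"] >= lo)).any()
                  for lo, hi in truth.true_mcr_intervals)
        recovered += hit
    return {"recovery_rate": recovered / n_replicates,
            "n_replicates": n_replicates}


def mcr_null_call_rate(n_replicates: int = 500, n_mutations: int = 10,
                       n_perm: int = 300, seed: int = 0) -> dict:
    """MCR call rate on uniform (clusterless) catalogs; should be <= alpha."""
    calls = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(n_mutations=n_mutations, cluster_weight=0.0,
                               seed=seed + rep)
        cat, _ = simulate_mutations(cfg)
        res = detect_mcrs(cat, n_perm=n_perm, seed=seed + rep)
        calls += not res.mcrs.empty
    return {"call_rate": calls / n_replicates, "n_replicates": n_replicates}


# --------------------------------------------------------------------------
# survival

def gbw_toy_example() -> dict:
    """The two-by-two hand example: events at 1,2 versus 3,4."""
    t = pd.DataFrame({"patient_id": ["a", "b", "c", "d"],
                      "time": [1.0, 2.0, 3.0, 4.0], "event": 1,
                      "expression": 0.0,
                      "group": ["high", "high", "low", "low"]})
    res = gbw_test(t)
    return {"chi_square": res.chi_square, "p": res.p}


def logrank_reduction_check(n_tables: int = 50, seed: int = 0) -> dict:
    """Max |difference| between weights=1 mode and the reference log-rank."""
    from lifelines.statistics import logrank_test
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_tables:
        n = int(rng.integers(20, 80))
        t = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "time": rng.exponential(5, n).round(3),
            "event": rng.integers(0, 2, n),
            "expression": 0.0,
            "group": rng.choice(["high", "low"], n)})
        if t["event"].sum() == 0 or t["group"].nunique() < 2:
            continue
        ours = gbw_test(t, weights="one")
        ref = logrank_test(
            t.loc[t.group == "high", "time"],
            t.loc[t.group == "low", "time"],
            t.loc[t.group == "high", "event"],
            t.loc[t.group == "low", "event"])
        worst = max(worst, abs(ours.chi_square - ref.test_statistic),
                    abs(ours.p - ref.p_value))
        done += 1
    return {"max_abs_diff": worst, "n_tables": n_tables}


def gbw_type_i_error(n_replicates: int = 500, n_patients: int = 200,
                     alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the GBW test when expression is unlinked to hazard."""
    rejections = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(hazard_log_ratio=0.0, n_patients=n_patients,
                               censor_rate=0.05, seed=seed + rep)
        table, _ = simulate_survival(cfg)
        res = gbw_test(quartile_groups(table))
        rejections += res.p < alpha
    return {"rejection_rate": rejections / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}


# --------------------------------------------------------------------------
# peak x expression integration

def promoter_direction_study(n_replicates: int = 100, n_genes: int = 150,
                             deg_fraction: float = 0.2, n_perm: int = 200,
                             seed: int = 0) -> dict:
    """How often planted promoter effects order the DEG-class fold-changes.

    Per replicate: full pipeline (simulate, quantile normalize, call DEGs,
    consensus, log2FC, region assignment, integration); success means the
    mean promoter-peak log2FC satisfies up > non_deg > down.
    """
    ordered = 0
    for rep in range(n_replicates):
        cfg = SimulationConfig(n_genes=n_genes, n_peaks=n_genes,
                               deg_fraction=deg_fraction,
                               library_size=1000 * n_genes,
                               seed=seed + rep)
        matrix, truth = simulate_expression(cfg)
        matrix = quantile_normalize(matrix)
        nulls = permutation_null(matrix, "K129R", "WT", n_perm=n_perm,
                                 seed=seed + rep)
        degs = call_degs(matrix, "K129R", "WT", nulls)
        ann = simulate_annotation(cfg)
        sets = simulate_peak_calls(cfg, ann, truth)
        table = cpm_log2(build_consensus(sets))
        peak_log2fc(table, "K129R")
        annotate_peaks(table, ann)
        rc = integrate_with_degs(table, degs, comparison="K129R_vs_WT")
        m = rc.class_means
        ordered += m["up"] > m["non_deg"] > m["down"]
    return {"ordered_fraction": ordered / n_replicates,
            "n_replicates": n_replicates}
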