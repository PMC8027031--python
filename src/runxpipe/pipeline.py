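"""End-to-end orchestration: simulate -> deg -> chip-integrate -> mcr -> survival.

Each stage validates its inputs before writing anything, writes TSV outputs
plus a JSON manifest entry (parameters, input hashes, row counts), and the
whole run is byte-reproducible under a fixed config.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import io as rio
from .annotation import read_gff_lite, write_gff_lite
from .clusters import detect_mcrs
from .config import PipelineConfig
from .expression import call_degs, permutation_null, quantile_normalize
from .peaks import (annotate_peaks, build_consensus, cpm_log2,
                    filter_low_count, integrate_with_degs, peak_log2fc)
from .simulate import (GroundTruth, simulate_annotation, simulate_expression,
                       simulate_mutations, simulate_peak_calls,
                       simulate_survival)
from .survival import gbw_test, km_estimate, quartile_groups

log = logging.getLogger("runxpipe")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: dict, name: str, params: dict[str, Any],
           outputs: dict[str, Path], rows: dict[str, int]) -> None:
    manifest["stages"].append({
        "stage": name,
        "parameters": params,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p),
                        "rows": rows.get(k)} for k, p in outputs.items()},
    })


def run_all(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns the manifest dict (also written)."""
    out = Path(config.outdir)
    inputs = out / "inputs"
    results = out / "results"
    manifest: dict[str, Any] = {"stages": []}
    t0 = time.time()

    if config.simulate:
        log.info("stage simulate: seed=%d", config.sim.seed)
        inputs.mkdir(parents=True, exist_ok=True)
        matrix, truth = simulate_expression(config.sim)
        annotation = simulate_annotation(config.sim)
        call_sets = simulate_peak_calls(config.sim, annotation, truth)
        catalog, t_mut = simulate_mutations(config.sim)
        surv, t_surv = simulate_survival(config.sim)
        truth.merge(t_mut).merge(t_surv)

        rio.write_expression(inputs / "expression.tsv", matrix)
        rio.write_sample_sheet(inputs / "samples.tsv", matrix)
        write_gff_lite(inputs / "annotation.gff.tsv", annotation)
        rio.write_peak_calls(inputs / "peaks", call_sets)
        rio.write_mutations(inputs / "mutations.tsv", catalog)
        rio.write_survival(inputs / "survival.tsv", surv)
        truth_dir = out / "truth"
        truth_dir.mkdir(parents=True, exist_ok=True)
        truth.deg_labels.rename_axis("gene_id").to_csv(
            truth_dir / "deg_labels.tsv", sep="\t")
        truth.peak_shift_labels.rename_axis("peak").to_frame().to_csv(
            truth_dir / "peak_shift_labels.tsv", sep="\t")
        _stage(manifest, "simulate",
               {"seed": config.sim.seed, "n_genes": config.sim.n_genes,
                "n_peaks": config.sim.n_peaks,
                "n_mutations": config.sim.n_mutations,
                "n_patients": config.sim.n_patients},
               {"expression": inputs / "expression.tsv",
                "samples": inputs / "samples.tsv",
                "annotation": inputs / "annotation.gff.tsv",
                "chip_samples": inputs / "peaks" / "chip_samples.tsv",
                "mutations": inputs / "mutations.tsv",
                "survival": inputs / "survival.tsv"},
               {"expression": config.sim.n_genes,
                "mutations": config.sim.n_mutations,
                "survival": config.sim.n_patients})

    results.mkdir(parents=True, exist_ok=True)

    # --- differential expression -----------------------------------------
    matrix = rio.read_expression(inputs / "expression.tsv",
                                 inputs / "samples.tsv")
    matrix = quantile_normalize(matrix)
    reference = config.sim.reference
    mutants = [c for c in pd.unique(matrix.conditions) if c != reference]
    deg_tables = {}
    for mutant in mutants:
        nulls = permutation_null(matrix, mutant, reference,
                                 n_perm=config.deg_n_perm, seed=config.seed)
        degs = call_degs(matrix, mutant, reference, nulls,
                         overall_p_max=config.overall_p_max,
                         t_p_max=config.t_p_max, lmr_min=config.lmr_min,
                         use_derived_lmr_cutoff=config.lmr_cutoff == "derived")
        degs.insert(0, "comparison", f"{mutant}_vs_{reference}")
        deg_tables[mutant] = degs
    deg_all = pd.concat(deg_tables.values()).rename_axis("gene_id")
    deg_path = results / "deg_results.tsv"
    deg_all.to_csv(deg_path, sep="\t")
    _stage(manifest, "deg",
           {"n_perm": config.deg_n_perm, "overall_p_max": config.overall_p_max,
            "t_p_max": config.t_p_max, "lmr_min": config.lmr_min,
            "lmr_cutoff": config.lmr_cutoff, "seed": config.seed},
           {"deg_results": deg_path}, {"deg_results": len(deg_all)})

    # --- ChIP-seq consensus + integration ---------------------------------
    annotation = read_gff_lite(inputs / "annotation.gff.tsv")
    call_sets = rio.read_peak_calls(inputs / "peaks",
                                    inputs / "peaks" / "chip_samples.tsv")
    call_sets = [filter_low_count(cs, config.min_reads) for cs in call_sets]
    table = build_consensus(call_sets, min_support=config.min_support)
    cpm_log2(table)
    for mutant in mutants:
        peak_log2fc(table, mutant, reference)
    annotate_peaks(table, annotation)

    cons = pd.concat([table.peaks, table.counts.add_prefix("count_"),
                      table.log2_cpm.add_prefix("log2cpm_"),
                      table.log2_fc.add_prefix("log2fc_")], axis=1)
    cons_path = results / "consensus_peaks.tsv"
    cons.to_csv(cons_path, sep="\t")

    integ_rows, binding_frames = [], []
    for mutant in mutants:
        comp = f"{mutant}_vs_{reference}"
        rc = integrate_with_degs(table, deg_tables[mutant], comparison=comp,
                                 region=config.region,
                                 binding_lfc_threshold=config.binding_lfc_threshold)
        integ_rows.append({
            "comparison": comp, "region": rc.region,
            "mean_log2fc_up": rc.class_means["up"],
            "mean_log2fc_down": rc.class_means["down"],
            "mean_log2fc_non_deg": rc.class_means["non_deg"],
            "anova_F": rc.anova_f, "anova_p": rc.anova_p})
        b = rc.deg_increased_binding.copy()
        b.insert(0, "comparison", comp)
        binding_frames.append(b)
    integ_path = results / "region_comparison.tsv"
    pd.DataFrame(integ_rows).to_csv(integ_path, sep="\t", index=False)
    binding_path = results / "deg_increased_promoter_binding.tsv"
    pd.concat(binding_frames, ignore_index=True).to_csv(
        binding_path, sep="\t", index=False)
    _stage(manifest, "chip_integrate",
           {"min_support": config.min_support, "min_reads": config.min_reads,
            "region": config.region,
            "binding_lfc_threshold": config.binding_lfc_threshold},
           {"consensus_peaks": cons_path, "region_comparison": integ_path,
            "deg_increased_promoter_binding": binding_path},
           {"consensus_peaks": len(cons)})

    # --- mutation clusters -------------------------------------------------
    catalog = rio.read_mutations(inputs / "mutations.tsv",
                                 protein_length=config.sim.protein_length)
    mcr = detect_mcrs(catalog, score_min=config.mcr_score_min,
                      min_mutated_residues=config.mcr_min_mutated_residues,
                      alpha=config.mcr_alpha, n_perm=config.mcr_n_perm,
                      seed=config.seed, window=config.mcr_window)
    scores_path = results / "cluster_scores.tsv"
    pd.DataFrame({"position_aa": range(1, len(mcr.scores) + 1),
                  "cluster_score": mcr.scores}).to_csv(scores_path, sep="\t",
                                                       index=False)
    mcr_path = results / "mcrs.tsv"
    mcr.mcrs.to_csv(mcr_path, sep="\t", index=False)
    _stage(manifest, "mcr",
           {"score_min": config.mcr_score_min,
            "min_mutated_residues": config.mcr_min_mutated_residues,
            "alpha": config.mcr_alpha, "n_perm": config.mcr_n_perm,
            "window": config.mcr_window, "seed": config.seed},
           {"cluster_scores": scores_path, "mcrs": mcr_path},
           {"mcrs": len(mcr.mcrs)})

    # --- survival ------------------------------------------------------------
    surv = rio.read_survival(inputs / "survival.tsv")
    surv = quartile_groups(surv, fraction=config.quartile_fraction)
    res = gbw_test(surv)
    gbw_path = results / "gbw_summary.tsv"
    pd.DataFrame([{"chi_square": res.chi_square, "p": res.p,
                   "weights": res.weights,
                   "significant": res.p < config.survival_alpha}]
                 ).to_csv(gbw_path, sep="\t", index=False)
    events_path = results / "gbw_event_table.tsv"
    res.table.to_csv(events_path, sep="\t", index=False)
    km_path = results / "km_curves.tsv"
    km = pd.concat([km_estimate(surv, g).assign(group=g)
                    for g in ("high", "low")], ignore_index=True)
    km.to_csv(km_path, sep="\t", index=False)
    _stage(manifest, "survival",
           {"quartile_fraction": config.quartile_fraction,
            "alpha": config.survival_alpha},
           {"gbw_summary": gbw_path, "gbw_event_table": events_path,
            "km_curves": km_path}, {"gbw_event_table": len(res.table)})

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    manifest["config"] = json.loads(json.dumps(
        {**config.__dict__, "sim": config.sim.__dict__}, default=str))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline finished in %.1fs; %d stages",
             manifest["elapsed_s"], len(manifest["stages"]))
    return manifest
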