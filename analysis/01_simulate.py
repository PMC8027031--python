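#!/usr/bin/env python
"""Generate the full set of synthetic study inputs.

Writes expression (3 conditions x 2 replicates), the toy genome annotation,
six ChIP/input peak-call sets, the protein mutation catalog, the survival
cohort, and the planted ground-truth labels under results/simulated/.
"""
from pathlib import Path

from runxpipe import io as rio
from runxpipe.annotation import write_gff_lite
from runxpipe.config import SimulationConfig
from runxpipe.simulate import (simulate_annotation, simulate_expression,
                               simulate_mutations, simulate_peak_calls,
                               simulate_survival)

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
CONFIG = SimulationConfig(seed=20260925)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    CONFIG.to_yaml(OUT / "config.yaml")

    matrix, truth = simulate_expression(CONFIG)
    annotation = simulate_annotation(CONFIG)
    call_sets = simulate_peak_calls(CONFIG, annotation, truth)
    catalog, t_mut = simulate_mutations(CONFIG)
    surv, t_surv = simulate_survival(CONFIG)
    truth.merge(t_mut).merge(t_surv)

    rio.write_expression(OUT / "expression.tsv", matrix)
    rio.write_sample_sheet(OUT / "samples.tsv", matrix)
    write_gff_lite(OUT / "annotation.gff.tsv", annotation)
    rio.write_peak_calls(OUT / "peaks", call_sets)
    rio.write_mutations(OUT / "mutations.tsv", catalog)
    rio.write_survival(OUT / "survival.tsv", surv)
    truth.deg_labels.rename_axis("gene_id").to_csv(
        OUT / "truth_deg_labels.tsv", sep="\t")
    truth.peak_shift_labels.rename_axis("peak").to_frame().to_csv(
        OUT / "truth_peak_shift_labels.tsv", sep="\t")

    lab = truth.deg_labels.iloc[:, 0].value_counts()
    print(f"simulated {CONFIG.n_genes} genes "
          f"({lab.get('up', 0)} up, {lab.get('down', 0)} down planted), "
          f"{CONFIG.n_peaks} peaks across {len(call_sets)} samples, "
          f"{CONFIG.n_mutations} mutations on a "
          f"{CONFIG.protein_length}-aa protein, "
          f"{CONFIG.n_patients} patients -> {OUT}")


if __name__ == "__main__":
    main()
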