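"""Plain-TSV readers and writers for every pipeline input and output.

Conventions: expression tables are gene_id + one column per sample;
peak-call tables are BED-like (chrom, start, end, name, read_count; 0-based
half-open); the gene annotation is GFF-lite (see
:mod:`runxpipe.annotation`; 1-based inclusive); mutation and survival
tables are flat TSVs.  Loaders validate schema and reject missing values.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .expression import ExpressionMatrix
from .simulate import MutationCatalog, PeakCallSet

EXPR_INDEX = "gene_id"


def _check_columns(df: pd.DataFrame, required: Sequence[str],
                   what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def write_expression(path: str | Path, matrix: ExpressionMatrix) -> None:
    matrix.values.rename_axis(EXPR_INDEX).to_csv(path, sep="\t")


def write_sample_sheet(path: str | Path, matrix: ExpressionMatrix) -> None:
    (matrix.conditions.rename("condition").rename_axis("sample_id")
     .to_frame().to_csv(path, sep="\t"))


def read_expression(expr_path: str | Path,
                    samples_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    if values.isna().any().any():
        raise ValueError(f"{expr_path}: missing values in expression matrix")
    sheet = pd.read_csv(samples_path, sep="\t")
    _check_columns(sheet, ["sample_id", "condition"], str(samples_path))
    conditions = sheet.set_index("sample_id")["condition"]
    unknown = set(values.columns) - set(conditions.index)
    if unknown:
        raise ValueError(f"{samples_path}: no condition for samples "
                         f"{sorted(unknown)}")
    return ExpressionMatrix(values=values, conditions=conditions)


def write_peak_calls(outdir: str | Path,
                     call_sets: Sequence[PeakCallSet]) -> Path:
    """One BED-like TSV per sample plus a chip sample sheet; returns sheet path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cs in call_sets:
        p = outdir / f"{cs.sample_id}.peaks.tsv"
        cs.intervals.to_csv(p, sep="\t", index=False)
        rows.append((cs.sample_id, cs.pair_id, cs.genotype, cs.library_size))
    sheet = outdir / "chip_samples.tsv"
    pd.DataFrame(rows, columns=["sample_id", "pair_id", "genotype",
                                "library_size"]).to_csv(sheet, sep="\t",
                                                        index=False)
    return sheet


def read_peak_calls(peaks_dir: str | Path,
                    sheet_path: str | Path) -> list[PeakCallSet]:
    sheet = pd.read_csv(sheet_path, sep="\t")
    _check_columns(sheet, ["sample_id", "pair_id", "genotype",
                           "library_size"], str(sheet_path))
    call_sets = []
    for row in sheet.itertuples():
        p = Path(peaks_dir) / f"{row.sample_id}.peaks.tsv"
        iv = pd.read_csv(p, sep="\t")
        _check_columns(iv, ["chrom", "start", "end", "name", "read_count"],
                       str(p))
        call_sets.append(PeakCallSet(
            sample_id=row.sample_id, pair_id=row.pair_id,
            genotype=row.genotype, library_size=int(row.library_size),
            intervals=iv))
    return call_sets


def write_mutations(path: str | Path, catalog: MutationCatalog) -> None:
    df = catalog.mutations.copy()
    df.insert(0, "protein_id", catalog.protein_id)
    df.to_csv(path, sep="\t", index=False)


def read_mutations(path: str | Path, protein_length: int) -> MutationCatalog:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["protein_id", "position_aa", "mutation_class",
                        "effect"], str(path))
    pids = df["protein_id"].unique()
    if len(pids) > 1:
        raise ValueError(f"{path}: multiple proteins {list(pids)}")
    return MutationCatalog(
        protein_id=str(pids[0]) if len(pids) else "protein",
        protein_length=protein_length,
        mutations=df[["position_aa", "mutation_class", "effect"]])


def write_survival(path: str | Path, table: pd.DataFrame) -> None:
    cols = ["patient_id", "time", "event", "expression"]
    table[cols].to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, ["patient_id", "time", "event", "expression"],
                   str(path))
    if df[["time", "event", "expression"]].isna().any().any():
        raise ValueError(f"{path}: missing values in survival table")
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative follow-up times")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0 or 1")
    return df
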