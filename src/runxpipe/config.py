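"""Configuration objects for the simulation and pipeline stages.

Every tunable of the synthetic-data generator lives in
:class:`SimulationConfig`; every stage parameter of the end-to-end pipeline
lives in :class:`PipelineConfig`.  Both round-trip through flat YAML files so
runs are fully described by a single text document.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import yaml


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic inputs with known ground truth.

    The defaults mirror the study design the pipeline targets: two biological
    replicates of three conditions (hypoxia-treated wild type and the two
    Runt-domain lysine mutants), log2-scale expression with i.i.d. Gaussian
    noise, duplicate ChIP/input peak-call pairs per genotype, a 415-residue
    protein with mutation hotspots near residues 129 and 171, and
    exponential survival with an expression-linked hazard.
    """

    n_genes: int = 1000
    conditions: tuple[str, ...] = ("WT", "K129R", "K171R")
    n_reps: int = 2
    deg_fraction: float = 0.1
    effect_size_log2: float = 1.0
    noise_sd: float = 0.25

    n_peaks: int = 1000
    peak_effect_log2: float = 1.0
    library_size: int = 1_000_000
    nb_dispersion: float = 0.05

    protein_length: int = 415
    n_mutations: int = 80
    cluster_centers: tuple[int, ...] = (129, 171)
    cluster_weight: float = 0.5

    n_patients: int = 400
    baseline_hazard: float = 0.1
    hazard_log_ratio: float = -0.5
    censor_rate: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_reps, int) or self.n_reps < 1:
            raise ValueError("n_reps must be a positive integer")
        for name in ("n_genes", "n_peaks", "protein_length", "library_size",
                     "n_patients"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not isinstance(self.n_mutations, int) or self.n_mutations < 0:
            raise ValueError("n_mutations must be a nonnegative integer")
        if len(self.conditions) < 2:
            raise ValueError("need a reference condition and >=1 mutant")
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must lie in [0, 1]")
        if not 0.0 <= self.cluster_weight <= 1.0:
            raise ValueError("cluster_weight must lie in [0, 1]")
        if self.effect_size_log2 < 0 or self.peak_effect_log2 < 0:
            raise ValueError("effect sizes are magnitudes; must be >= 0")
        for name in ("noise_sd", "nb_dispersion", "baseline_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        for c in self.cluster_centers:
            if not 1 <= c <= self.protein_length:
                raise ValueError(
                    f"cluster center {c} outside protein [1, {self.protein_length}]")

    @property
    def reference(self) -> str:
        return self.conditions[0]

    @property
    def mutants(self) -> tuple[str, ...]:
        return tuple(self.conditions[1:])

    @property
    def comparisons(self) -> tuple[str, ...]:
        return tuple(f"{m}_vs_{self.reference}" for m in self.mutants)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["cluster_centers"] = list(self.cluster_centers)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        if "cluster_centers" in d:
            d["cluster_centers"] = tuple(d["cluster_centers"])
        return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    """Flat stage-by-stage parameters for the end-to-end run.

    Defaults are the study's stated cutoffs: overall p < 0.01, t-test
    p < 0.1, |log2-median-ratio| > 0.406, consensus support >= 2 of 6 pairs,
    read-count filter at <= 20, cluster score >= 3 with >= 5 mutated
    residues at permutation p < 0.05, and top/bottom 25% survival groups.
    """

    outdir: str = "pipeline_out"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    # differential expression
    deg_n_perm: int = 1000
    overall_p_max: float = 0.01
    t_p_max: float = 0.1
    lmr_min: float = 0.406
    lmr_cutoff: str = "fixed"  # "fixed" or "derived"

    # ChIP-seq integration
    min_support: int = 2
    min_reads: int = 20
    region: str = "promoter"
    binding_lfc_threshold: float = 0.0

    # mutation clusters
    mcr_score_min: int = 3
    mcr_min_mutated_residues: int = 5
    mcr_alpha: float = 0.05
    mcr_n_perm: int = 10000
    mcr_window: int = 1

    # survival
    quartile_fraction: float = 0.25
    survival_alpha: float = 0.05

    seed: int = 0

    def __post_init__(self) -> None:
        if self.lmr_cutoff not in ("fixed", "derived"):
            raise ValueError("lmr_cutoff must be 'fixed' or 'derived'")
        for name in ("overall_p_max", "t_p_max", "lmr_min", "mcr_alpha",
                     "survival_alpha", "quartile_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_support < 1 or self.mcr_score_min < 1:
            raise ValueError("support and score minima must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["sim"]["conditions"] = list(self.sim.conditions)
        d["sim"]["cluster_centers"] = list(self.sim.cluster_centers)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("sim", {})
        if "conditions" in sim:
            sim["conditions"] = tuple(sim["conditions"])
        if "cluster_centers" in sim:
            sim["cluster_centers"] = tuple(sim["cluster_centers"])
        return cls(sim=SimulationConfig(**sim), **d)
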