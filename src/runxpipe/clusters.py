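"""Scan-statistic mutation clustering on protein coordinates.

The per-residue cluster score is the number of mutations at that residue
plus its immediate neighbors (a sliding window of three; a five-residue
window is available as an option).  Significance of the catalog's maximum
score comes from a permutation test that re-places the same number of
mutations uniformly at random over the protein.  Mutation cluster regions
(MCRs) are maximal runs of residues with score >= 1 whose maximum score and
distinct-mutated-residue count pass their cutoffs while the catalog-level
permutation p is below alpha.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MutationCatalog

__all__ = [
    "MutationClusterResult",
    "filter_catalog",
    "cluster_scores",
    "max_score_permutation_p",
    "detect_mcrs",
]


@dataclass
class MutationClusterResult:
    scores: np.ndarray           # per-residue window score, length = protein
    mcrs: pd.DataFrame           # start_aa, end_aa, max_score, n_mutated_residues, perm_p
    perm_p: float                # catalog-level permutation p of the max score
    n_perm: int
    seed: int


def filter_catalog(catalog: MutationCatalog, nonsyn_only: bool = False,
                   include_indels: bool = True) -> MutationCatalog:
    """Optionally restrict to non-synonymous events and/or drop INDELs."""
    m = catalog.mutations
    if nonsyn_only:
        m = m[m["effect"] == "non_synonymous"]
    if not include_indels:
        m = m[m["mutation_class"] == "SNV"]
    return MutationCatalog(catalog.protein_id, catalog.protein_length,
                           m.reset_index(drop=True))


def _window_sum(counts: np.ndarray, window: int) -> np.ndarray:
    """Sliding sum over +-window residues, truncated at the bounds."""
    kernel = np.ones(2 * window + 1)
    return np.convolve(counts, kernel, mode="same")


def cluster_scores(catalog: MutationCatalog, window: int = 1) -> np.ndarray:
    """Per-residue score: mutations at the residue and its neighbors.

    ``window=1`` is the default three-residue window (the residue and one
    neighbor on each side); ``window=2`` gives the five-residue variant.
    """
    counts = np.bincount(
        catalog.mutations["position_aa"].to_numpy(dtype=np.int64),
        minlength=catalog.protein_length + 1)[1:]
    return _window_sum(counts, window).astype(int)


def max_score_permutation_p(catalog: MutationCatalog, n_perm: int = 10000,
                            seed: int = 0, window: int = 1) -> float:
    """Permutation p of the observed maximum cluster score.

    Null: the same number of mutations is placed uniformly at random (with
    replacement) over the protein; p uses the +1 correction so it is never
    zero.
    """
    m = len(catalog)
    if m < 1:
        raise ValueError("catalog has no mutations")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p")
    observed = int(cluster_scores(catalog, window=window).max())
    rng = np.random.default_rng(seed)
    L = catalog.protein_length
    n_ge = 0
    batch = max(1, min(n_perm, 4_000_000 // max(L, 1)))
    done = 0
    kernel = np.ones(2 * window + 1)
    while done < n_perm:
        b = min(batch, n_perm - done)
        pos = rng.integers(0, L, size=(b, m))
        counts = np.zeros((b, L))
        np.add.at(counts, (np.repeat(np.arange(b), m), pos.ravel()), 1.0)
        # windowed sums via padded cumulative sums, per row
        padded = np.zeros((b, L + 2 * window))
        padded[:, window:window + L] = counts
        csum = np.cumsum(padded, axis=1)
        win = np.empty((b, L))
        width = 2 * window + 1
        win[:, 0] = csum[:, width - 1]
        win[:, 1:] = csum[:, width:] - csum[:, :L - 1]
        n_ge += int((win.max(axis=1) >= observed).sum())
        done += b
    return (1.0 + n_ge) / (1.0 + n_perm)


def detect_mcrs(catalog: MutationCatalog, score_min: int = 3,
                min_mutated_residues: int = 5, alpha: float = 0.05,
                n_perm: int = 10000, seed: int = 0,
                window: int = 1) -> MutationClusterResult:
    """Call mutation cluster regions.

    Candidate regions are maximal runs of consecutive residues with score
    >= 1 (so candidates are separated by at least ``2*window + 1``
    mutation-free residues).  A candidate is an MCR iff its maximum score is
    >= ``score_min``, it contains >= ``min_mutated_residues`` distinct
    mutated residues, and the catalog-level permutation p is < ``alpha``.
    Recurrent mutations count multiply in scores but once toward the
    residue count.
    """
    scores = cluster_scores(catalog, window=window)
    cols = ["start_aa", "end_aa", "max_score", "n_mutated_residues", "perm_p"]
    if len(catalog) == 0:
        return MutationClusterResult(
            scores=scores, mcrs=pd.DataFrame(columns=cols), perm_p=1.0,
            n_perm=n_perm, seed=seed)
    perm_p = max_score_permutation_p(catalog, n_perm=n_perm, seed=seed,
                                     window=window)
    mutated = np.unique(catalog.mutations["position_aa"].to_numpy())
    rows = []
    nonzero = scores > 0
    # maximal runs of score >= 1
    boundaries = np.flatnonzero(np.diff(np.r_[0, nonzero.view(np.int8), 0]))
    for lo, hi in zip(boundaries[::2], boundaries[1::2]):  # [lo, hi) 0-based
        start_aa, end_aa = lo + 1, hi
        max_score = int(scores[lo:hi].max())
        n_res = int(((mutated >= start_aa) & (mutated <= end_aa)).sum())
        if (max_score >= score_min and n_res >= min_mutated_residues
                and perm_p < alpha):
            rows.append((start_aa, end_aa, max_score, n_res, perm_p))
    return MutationClusterResult(
        scores=scores,
        mcrs=pd.DataFrame(rows, columns=cols),
        perm_p=perm_p, n_perm=n_perm, seed=seed)
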