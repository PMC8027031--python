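"""Integrative differential-expression statistic.

The statistic combines, per gene and per two-group comparison, a
pooled-variance Student t and a log2-median-ratio (LMR).  Empirical null
distributions for both are estimated by permuting the sample labels of the
compared groups and pooling the permuted statistics across all genes
(per-gene nulls are meaningless at two or three replicates per condition).
The two empirical p-values are combined with Stouffer's method and a gene is
called differentially expressed when the combined p, the parametric t-test p
and the absolute LMR all pass their cutoffs, with the LMR sign giving the
direction.

Default cutoffs: overall p < 0.01, t-test p < 0.1, |LMR| > 0.406
(a 1.33-fold change); the LMR cutoff can instead be derived from the
permutation null as the mean of the absolute 1st and 99th percentiles.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "NullDistributions",
    "quantile_normalize",
    "quantile_normalize_frame",
    "gene_statistics",
    "permutation_null",
    "empirical_p",
    "stouffer",
    "call_degs",
]

# Cap for the t statistic of degenerate zero-within-group-variance genes;
# keeps pooled permutation nulls finite.
T_CAP = 1e6
_P_FLOOR = 1e-300


@dataclass
class ExpressionMatrix:
    """Gene x sample log2-scale expression with condition labels.

    ``values`` is genes in rows, samples in columns; ``conditions`` maps each
    sample id to its condition label.
    """

    values: pd.DataFrame
    conditions: pd.Series
    normalized: bool = False

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        self.conditions = self.conditions.loc[list(self.values.columns)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, condition: str) -> list[str]:
        s = [c for c in self.values.columns if self.conditions[c] == condition]
        if not s:
            raise ValueError(f"condition {condition!r} has no samples")
        return s


@dataclass
class NullDistributions:
    """Pooled permutation nulls of the t statistic and the LMR."""

    t_null: np.ndarray
    lmr_null: np.ndarray
    n_perm: int
    seed: int
    exhaustive: bool
    lmr_cutoff_derived: float = field(init=False)

    def __post_init__(self) -> None:
        if self.t_null.size == 0 or self.lmr_null.size == 0:
            raise ValueError("null samples must be non-empty")
        lo, hi = np.percentile(self.lmr_null, [1, 99])
        self.lmr_cutoff_derived = float((abs(lo) + abs(hi)) / 2.0)


def quantile_normalize_frame(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the shared per-rank across-column means."""
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 columns")
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("matrix contains missing values; impute or drop first")
    order = np.argsort(arr, axis=0, kind="stable")
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = rank_means
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize the matrix; labels unchanged, flag set."""
    return ExpressionMatrix(
        values=quantile_normalize_frame(matrix.values),
        conditions=matrix.conditions,
        normalized=True,
    )


def _t_and_lmr(values: np.ndarray, ia: np.ndarray, ib: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    A, B = values[:, ia], values[:, ib]
    na, nb = len(ia), len(ib)
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero pooled variance: t := 0 when means agree, capped otherwise
    degenerate = se == 0
    if degenerate.any():
        t = np.where(degenerate, np.sign(diff) * T_CAP, t)
        t = np.where(degenerate & (diff == 0), 0.0, t)
    lmr = np.median(A, axis=1) - np.median(B, axis=1)
    return t, lmr


def gene_statistics(matrix: ExpressionMatrix, group_a: str, group_b: str
                    ) -> pd.DataFrame:
    """Per-gene pooled-variance t, its two-sided p, and the LMR.

    ``t_stat`` is group_a minus group_b; ``lmr`` is the difference of
    within-group medians of the log2 values.
    """
    ia = np.array([matrix.values.columns.get_loc(s)
                   for s in matrix.samples_of(group_a)])
    ib = np.array([matrix.values.columns.get_loc(s)
                   for s in matrix.samples_of(group_b)])
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need >= 2 samples for a t test")
    t, lmr = _t_and_lmr(matrix.values.to_numpy(dtype=float), ia, ib)
    df = len(ia) + len(ib) - 2
    t_p = np.clip(2.0 * stats.t.sf(np.abs(t), df), _P_FLOOR, 1.0)
    return pd.DataFrame(
        {"t_stat": t, "t_p": t_p, "lmr": lmr}, index=matrix.gene_ids)


def _distinct_splits(n: int, na: int, symmetric: bool) -> int:
    total = math.comb(n, na)
    if symmetric:
        total //= 2
    return total - 1  # the identity split is excluded from the null


def permutation_null(matrix: ExpressionMatrix, group_a: str, group_b: str,
                     n_perm: int = 1000, seed: int = 0) -> NullDistributions:
    """Pooled permutation null of (t, LMR) over the two compared groups.

    Sample labels of the combined groups are shuffled jointly; the per-gene
    statistics of every permutation are pooled across genes.  When the design
    admits fewer distinct label splits than ``n_perm`` (always the case for
    the 2v2 and 3v3 designs here), all distinct non-identity splits are
    enumerated instead and ``n_perm`` records that count.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    sa, sb = matrix.samples_of(group_a), matrix.samples_of(group_b)
    cols = sa + sb
    idx = np.array([matrix.values.columns.get_loc(s) for s in cols])
    values = matrix.values.to_numpy(dtype=float)
    na, n = len(sa), len(cols)
    symmetric = na == n - na

    splits: list[tuple[np.ndarray, np.ndarray]] = []
    n_distinct = _distinct_splits(n, na, symmetric)
    exhaustive = n_distinct <= n_perm
    if exhaustive:
        identity = tuple(range(na))
        for comb in combinations(range(n), na):
            if comb == identity:
                continue
            if symmetric and 0 not in comb:
                continue  # complement already represented
            rest = [i for i in range(n) if i not in comb]
            splits.append((idx[list(comb)], idx[rest]))
        assert len(splits) == n_distinct
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            splits.append((idx[perm[:na]], idx[perm[na:]]))

    t_pool, lmr_pool = [], []
    for ia, ib in splits:
        t, lmr = _t_and_lmr(values, ia, ib)
        t_pool.append(t)
        lmr_pool.append(lmr)
    return NullDistributions(
        t_null=np.clip(np.concatenate(t_pool), -T_CAP, T_CAP),
        lmr_null=np.concatenate(lmr_pool),
        n_perm=len(splits),
        seed=seed,
        exhaustive=exhaustive,
    )


def empirical_p(observed, null_sample) -> np.ndarray | float:
    """Two-sided pooled-null empirical p with the +1 correction.

    p = (1 + #{x in null : |x| >= |observed|}) / (1 + |null|), so p is never
    exactly zero and the normal quantile used by Stouffer stays finite.
    """
    null_abs = np.sort(np.abs(np.asarray(null_sample, dtype=float)))
    if null_abs.size == 0:
        raise ValueError("null sample is empty")
    obs = np.abs(np.asarray(observed, dtype=float))
    n_ge = null_abs.size - np.searchsorted(null_abs, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + null_abs.size)
    return float(p) if np.isscalar(observed) else p


def stouffer(p_a, p_b) -> np.ndarray | float:
    """Combine two p-values via equal-weight Stouffer z averaging.

    An exactly-uninformative p of 1.0 contributes z = 0 (no evidence)
    rather than the literal normal quantile of 0, which would veto the
    other p with -infinity.
    """
    pa = np.asarray(p_a, dtype=float)
    pb = np.asarray(p_b, dtype=float)
    for p in (pa, pb):
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("p-values must lie in (0, 1]")
    za = np.where(pa >= 1.0, 0.0, stats.norm.isf(pa))
    zb = np.where(pb >= 1.0, 0.0, stats.norm.isf(pb))
    z = (za + zb) / math.sqrt(2.0)
    out = np.clip(stats.norm.sf(z), _P_FLOOR, 1.0)
    return float(out) if (np.isscalar(p_a) and np.isscalar(p_b)) else out


def call_degs(matrix: ExpressionMatrix, group_a: str, group_b: str,
              nulls: NullDistributions,
              overall_p_max: float = 0.01,
              t_p_max: float = 0.1,
              lmr_min: float = 0.406,
              use_derived_lmr_cutoff: bool = False) -> pd.DataFrame:
    """Three-criterion DEG table for group_a versus group_b.

    A gene is ``up`` iff overall_p < overall_p_max, t_p < t_p_max and
    |lmr| > the LMR cutoff with lmr > 0; ``down`` symmetric; else
    ``non_deg``.  Every intermediate quantity is reported so the call is
    re-derivable from the table alone.
    """
    if min(overall_p_max, t_p_max, lmr_min) <= 0:
        raise ValueError("thresholds must be positive")
    res = gene_statistics(matrix, group_a, group_b)
    res["p_t_emp"] = empirical_p(res["t_stat"].to_numpy(), nulls.t_null)
    res["p_lmr_emp"] = empirical_p(res["lmr"].to_numpy(), nulls.lmr_null)
    res["overall_p"] = stouffer(res["p_t_emp"].to_numpy(),
                                res["p_lmr_emp"].to_numpy())
    cutoff = nulls.lmr_cutoff_derived if use_derived_lmr_cutoff else lmr_min
    res.attrs["lmr_cutoff"] = cutoff
    res.attrs["comparison"] = f"{group_a}_vs_{group_b}"
    passing = ((res["overall_p"] < overall_p_max)
               & (res["t_p"] < t_p_max)
               & (res["lmr"].abs() > cutoff))
    res["call"] = np.where(passing & (res["lmr"] > 0), "up",
                           np.where(passing & (res["lmr"] < 0), "down",
                                    "non_deg"))
    return res
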