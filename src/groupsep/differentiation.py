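"""Nucleotide diversity and the coefficient of nucleotide differentiation.

For two groups of strains, N_st = (R_t − R_s)/R_t, where R_t is the
mean pairwise p-distance over the pooled sample (every pair, within and
between groups) and R_s combines the within-group diversities —
pair-weighted by default, i.e. every within-group pair counts equally
regardless of group size.  Sampling noise can make R_s exceed R_t, so
N_st may be negative; it is reported as computed, never clipped.

Uncertainty comes from a seeded nonparametric bootstrap over alignment
columns: each replicate resamples columns with replacement to the
original length and recomputes N_st; the 95% interval is the 2.5/97.5
percentile of the replicate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distances import DistanceError, encode_alignment
from .sequence_io import ConcatenateAlignment, LocusAlignment

WEIGHTINGS = ("pair_weighted", "group_mean")
BOOTSTRAP_UNITS = ("site", "strain")


@dataclass
class DiversityResult:
    """Mean pairwise p-distance within a strain subset.

    ``pair_matrix`` retains the subset's full pairwise distance matrix
    (members in ``members`` order) so hierarchical resampling over
    strains stays possible downstream.
    """

    scope: str
    locus_or_concat: str
    mean_pairwise_distance: float
    n_pairs: int
    members: list[str] = field(default_factory=list)
    pair_matrix: np.ndarray | None = None


@dataclass
class DifferentiationResult:
    group_a: str
    group_b: str
    locus_or_concat: str
    R_t: float
    R_s: float
    N_st: float
    bootstrap_values: np.ndarray | None = None
    ci95: tuple[float, float] | None = None
    n_boot: int = 0
    n_undefined_reps: int = 0


def _pair_site_indicators(
    aln: LocusAlignment | ConcatenateAlignment, strain_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair, per-column boolean mismatch / comparable matrices.

    Rows follow ``itertools.combinations(range(n), 2)`` order; these are
    the sufficient statistics for any column-resampled p-distance.
    """
    all_ids, X_all = encode_alignment(aln)
    pos = {s: k for k, s in enumerate(all_ids)}
    missing = [s for s in strain_ids if s not in pos]
    if missing:
        raise ValueError(f"strains not in alignment: {missing}")
    X = X_all[[pos[s] for s in strain_ids]]
    n = len(strain_ids)
    iu, ju = np.triu_indices(n, k=1)
    A = X[iu]  # (n_pairs, L)
    B = X[ju]
    comparable = (A != 255) & (B != 255)
    mismatch = (A != B) & comparable
    return mismatch, comparable


def _pair_p_from_indicators(
    mismatch: np.ndarray, comparable: np.ndarray, cols: np.ndarray | None = None
) -> np.ndarray:
    """Per-pair p-distance, optionally on a resampled column index set.

    Pairs with zero comparable sites come back as NaN.
    """
    if cols is not None:
        m = mismatch[:, cols].sum(axis=1)
        c = comparable[:, cols].sum(axis=1)
    else:
        m = mismatch.sum(axis=1)
        c = comparable.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(c > 0, m / np.maximum(c, 1), np.nan)


def nucleotide_diversity(
    aln: LocusAlignment | ConcatenateAlignment,
    strain_subset: Sequence[str],
    scope: str = "pooled",
) -> DiversityResult:
    """Mean pairwise p-distance over all unordered pairs in the subset."""
    ids = list(strain_subset)
    if len(ids) < 2:
        raise ValueError("nucleotide diversity needs at least 2 strains")
    mismatch, comparable = _pair_site_indicators(aln, ids)
    p = _pair_p_from_indicators(mismatch, comparable)
    if np.isnan(p).any():
        iu, ju = np.triu_indices(len(ids), k=1)
        bad = int(np.flatnonzero(np.isnan(p))[0])
        raise DistanceError(
            f"no comparable sites between {ids[iu[bad]]!r} and {ids[ju[bad]]!r}"
        )
    n = len(ids)
    dm = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    dm[iu, ju] = p
    dm += dm.T
    return DiversityResult(
        scope=scope,
        locus_or_concat=getattr(aln, "locus_name", "?"),
        mean_pairwise_distance=float(p.mean()),
        n_pairs=len(p),
        members=ids,
        pair_matrix=dm,
    )


def _group_layout(groups: Mapping[str, Sequence[str]]) -> tuple[list[str], list[str], np.ndarray]:
    """Canonical strain order and per-pair group structure.

    Returns (group labels, pooled strain ids, pair code) where pair code
    is 0 for a within-group-a pair, 1 within-group-b, 2 between.
    """
    if len(groups) != 2:
        raise ValueError("N_st is defined for exactly 2 groups")
    (la, mem_a), (lb, mem_b) = groups.items()
    mem_a, mem_b = list(mem_a), list(mem_b)
    if len(mem_a) < 2 or len(mem_b) < 2:
        raise ValueError("each group needs at least 2 strains")
    if set(mem_a) & set(mem_b):
        raise ValueError("groups overlap")
    ids = mem_a + mem_b
    is_a = np.array([s in set(mem_a) for s in ids])
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    code = np.where(
        is_a[iu] & is_a[ju], 0, np.where(~is_a[iu] & ~is_a[ju], 1, 2)
    )
    return [la, lb], ids, code


def _nst_from_p(p: np.ndarray, code: np.ndarray, weighting: str) -> tuple[float, float, float]:
    """(R_t, R_s, N_st) from per-pair p-distances and pair group codes."""
    R_t = float(np.nanmean(p))
    within = p[code != 2]
    if weighting == "pair_weighted":
        R_s = float(np.nanmean(within))
    else:  # group_mean
        R_s = float(
            (np.nanmean(p[code == 0]) + np.nanmean(p[code == 1])) / 2.0
        )
    if R_t == 0:
        raise DistanceError("no diversity: N_st undefined")
    return R_t, R_s, (R_t - R_s) / R_t


def nst(
    aln: LocusAlignment | ConcatenateAlignment,
    groups: Mapping[str, Sequence[str]],
    weighting: str = "pair_weighted",
) -> DifferentiationResult:
    """Point estimate of N_st for one group pair on one locus/concatenate."""
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    labels, ids, code = _group_layout(groups)
    mismatch, comparable = _pair_site_indicators(aln, ids)
    p = _pair_p_from_indicators(mismatch, comparable)
    if np.isnan(p).any():
        raise DistanceError("pair with no comparable sites")
    R_t, R_s, n_st = _nst_from_p(p, code, weighting)
    return DifferentiationResult(
        labels[0], labels[1], getattr(aln, "locus_name", "?"), R_t, R_s, n_st
    )


def nst_bootstrap(
    aln: LocusAlignment | ConcatenateAlignment,
    groups: Mapping[str, Sequence[str]],
    n_boot: int = 1000,
    seed: int = 0,
    weighting: str = "pair_weighted",
    unit: str = "site",
) -> DifferentiationResult:
    """N_st with a seeded bootstrap (columns by default, strains by flag).

    The point estimate comes from the unresampled data.  Replicates in
    which the pooled sample shows no diversity (R_t = 0) are undefined;
    they are counted and excluded from the interval, and more than 50%
    undefined replicates is an error.
    """
    if unit not in BOOTSTRAP_UNITS:
        raise ValueError(f"unit must be one of {BOOTSTRAP_UNITS}")
    point = nst(aln, groups, weighting)
    labels, ids, code = _group_layout(groups)
    mismatch, comparable = _pair_site_indicators(aln, ids)
    L = mismatch.shape[1]
    rng = np.random.default_rng(seed)
    values: list[float] = []
    n_undef = 0
    if unit == "site":
        for _ in range(n_boot):
            cols = rng.integers(0, L, size=L)
            p = _pair_p_from_indicators(mismatch, comparable, cols)
            try:
                if np.isnan(p).any():
                    raise DistanceError("undefined pair")
                values.append(_nst_from_p(p, code, weighting)[2])
            except DistanceError:
                n_undef += 1
    else:
        (la, mem_a), (lb, mem_b) = groups.items()
        mem_a, mem_b = list(mem_a), list(mem_b)
        full_p = _pair_p_from_indicators(mismatch, comparable)
        n = len(ids)
        dm = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        dm[iu, ju] = full_p
        dm += dm.T
        pos = {s: k for k, s in enumerate(ids)}
        for _ in range(n_boot):
            ra = rng.choice([pos[s] for s in mem_a], size=len(mem_a), replace=True)
            rb = rng.choice([pos[s] for s in mem_b], size=len(mem_b), replace=True)
            sel = np.concatenate([ra, rb])
            sub = dm[np.ix_(sel, sel)]
            p_rep = sub[np.triu_indices(len(sel), k=1)]
            try:
                values.append(_nst_from_p(p_rep, code, weighting)[2])
            except DistanceError:
                n_undef += 1
    if n_undef > n_boot / 2:
        raise DistanceError("alignment too invariant for bootstrap")
    arr = np.array(values)
    ci = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return DifferentiationResult(
        labels[0], labels[1], point.locus_or_concat,
        point.R_t, point.R_s, point.N_st,
        bootstrap_values=arr, ci95=ci, n_boot=n_boot, n_undefined_reps=n_undef,
    )


def _resample_diversity(res: DiversityResult, rng: np.random.Generator) -> float:
    """Mean pairwise distance after resampling the subset's strains."""
    k = len(res.members)
    idx = rng.integers(0, k, size=k)
    sub = res.pair_matrix[np.ix_(idx, idx)]
    return float(sub[np.triu_indices(k, k=1)].mean())


def compare_category_diversity(
    hkg_diversities: Sequence[DiversityResult],
    sym_diversities: Sequence[DiversityResult],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Ratio of mean sym to mean hkg diversity, with a hierarchical bootstrap CI.

    Each replicate resamples loci with replacement within each category
    and, when a diversity result retains its pairwise matrix, resamples
    strains within each sampled locus as well.
    """
    if not hkg_diversities or not sym_diversities:
        raise ValueError("need at least one locus per category")
    hkg_means = np.array([d.mean_pairwise_distance for d in hkg_diversities])
    sym_means = np.array([d.mean_pairwise_distance for d in sym_diversities])
    if hkg_means.mean() == 0:
        raise DistanceError("zero mean hkg diversity: ratio undefined")
    ratio = float(sym_means.mean() / hkg_means.mean())
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        h_idx = rng.integers(0, len(hkg_diversities), size=len(hkg_diversities))
        s_idx = rng.integers(0, len(sym_diversities), size=len(sym_diversities))
        h_vals = [
            _resample_diversity(hkg_diversities[i], rng)
            if hkg_diversities[i].pair_matrix is not None
            else hkg_diversities[i].mean_pairwise_distance
            for i in h_idx
        ]
        s_vals = [
            _resample_diversity(sym_diversities[i], rng)
            if sym_diversities[i].pair_matrix is not None
            else sym_diversities[i].mean_pairwise_distance
            for i in s_idx
        ]
        h_mean = float(np.mean(h_vals))
        if h_mean > 0:
            reps.append(float(np.mean(s_vals)) / h_mean)
    if not reps:
        raise DistanceError("all bootstrap replicates had zero hkg diversity")
    ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    return ratio, ci
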