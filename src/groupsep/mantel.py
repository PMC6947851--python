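"""Mantel correlation between genetic and geographic distance matrices.

The statistic is the Pearson product-moment correlation over the
n(n−1)/2 upper-triangle entries of the two matrices after aligning them
on strain id.  The null distribution permutes the rows and columns of
one matrix simultaneously; the p-value uses the add-one convention
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm), one-sided against a
positive association by default (the two-sided variant doubles-counts
permutations at least as extreme in |r|).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .distances import DistanceMatrix, distance_matrix, geographic_matrix
from .sequence_io import ConcatenateAlignment, LocusAlignment, StrainMetadata

ALTERNATIVES = ("greater", "two-sided")


@dataclass
class MantelResult:
    locus_or_concat: str
    r: float
    p_value: float
    n_perm: int
    seed: int
    n_strains: int
    error: str | None = None


def _aligned_triangles(
    a: DistanceMatrix, b: DistanceMatrix
) -> tuple[list[str], np.ndarray, np.ndarray]:
    if set(a.ids) != set(b.ids):
        raise ValueError(
            f"mismatched strain sets: {sorted(set(a.ids) ^ set(b.ids))}"
        )
    # canonical sorted order: permutations (and hence p-values) do not
    # depend on the order strains arrived in
    ids = sorted(a.ids)
    return ids, a.reorder(ids).values, b.reorder(ids).values


def mantel_test(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
    locus_or_concat: str = "?",
) -> MantelResult:
    """Permutation Mantel test; deterministic given the seed."""
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    ids, A, B = _aligned_triangles(genetic, geographic)
    n = len(ids)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 strains")
    iu = np.triu_indices(n, k=1)
    x = A[iu]
    y = B[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance in a distance matrix")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xc * yc))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = A[np.ix_(perm, perm)][iu]
        r_perm = float(np.corrcoef(xp, y)[0, 1])
        if alternative == "greater":
            if r_perm >= r_obs:
                count += 1
        else:
            if abs(r_perm) >= abs(r_obs):
                count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(locus_or_concat, r_obs, p, n_perm, seed, n)


def mantel_panel(
    loci: Sequence[LocusAlignment | ConcatenateAlignment],
    meta: Sequence[StrainMetadata],
    model: str = "p_distance",
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> list[MantelResult]:
    """One Mantel test per locus/concatenate against shared geography.

    Per-locus seeds are derived as ``seed + locus index`` so a subset
    rerun reproduces the full panel's values.  A locus whose genetic
    matrix is degenerate (e.g. all sequences identical) yields a result
    carrying ``r = nan`` rather than aborting the whole panel.
    """
    results: list[MantelResult] = []
    for k, aln in enumerate(loci):
        strains = [m for m in meta if m.strain_id in aln.sequences]
        geo = geographic_matrix(strains)
        try:
            gen = distance_matrix(aln, model).reorder(geo.ids)
            results.append(
                mantel_test(
                    gen, geo, n_perm=n_perm, seed=seed + k,
                    alternative=alternative,
                    locus_or_concat=getattr(aln, "locus_name", f"locus_{k}"),
                )
            )
        except ValueError as e:
            results.append(
                MantelResult(
                    getattr(aln, "locus_name", f"locus_{k}"),
                    float("nan"), float("nan"), n_perm, seed + k, len(strains),
                    error=f"{getattr(aln, 'locus_name', k)}: {e}",
                )
            )
    return results
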