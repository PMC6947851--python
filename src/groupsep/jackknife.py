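"""Leave-one-out nearest-group assignment (jackknife), asymmetry and CAD.

Each strain is removed from the pool and assigned to the group whose
remaining members it is most similar to on average, where similarity is
100·(1 − distance) in percent.  The tested strain is excluded from its
own group's average, otherwise self-similarity would trivially win.
Exact ties are broken uniformly at random with a seeded generator;
iteration is in sorted strain-id order so results never depend on input
order.

The per-group assignment percentages form a (generally asymmetric)
matrix: group g's row says where g's members land.  The coefficient of
average divergence, CAD(g) = 100 − mean leave-one-out within-group
similarity of g, measures within-group heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

ASSIGN_MODES = ("group_mean", "nearest_neighbor")
CAD_DEFINITIONS = ("similarity", "assignment")


@dataclass
class JKResult:
    groups: list[str]
    assignment_pct: np.ndarray          # row g, col h: % of g assigned to h
    avg_similarity: np.ndarray          # (g,h) mean pairwise similarity %, LOO diag
    cad: dict[str, float]
    n_ties: int
    seed: int
    locus_or_concat: str = "?"
    audit: pd.DataFrame | None = field(default=None, repr=False)


def jk_assign(
    dm: DistanceMatrix,
    groups: Mapping[str, Sequence[str]],
    seed: int = 0,
    mode: str = "group_mean",
    cad_from: str = "similarity",
    locus_or_concat: str = "?",
) -> JKResult:
    """Run the leave-one-out nearest-group classification on a distance matrix.

    ``mode="group_mean"`` (default) assigns to the group with the highest
    mean similarity; ``"nearest_neighbor"`` to the group holding the
    single most similar strain (sensitivity analysis).
    """
    if mode not in ASSIGN_MODES:
        raise ValueError(f"mode must be one of {ASSIGN_MODES}")
    if cad_from not in CAD_DEFINITIONS:
        raise ValueError(f"cad_from must be one of {CAD_DEFINITIONS}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    members = {g: list(v) for g, v in groups.items()}
    for g, mem in members.items():
        if len(mem) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
        absent = [s for s in mem if s not in dm.ids]
        if absent:
            raise ValueError(f"strains missing from distance matrix: {absent}")
    sim = 100.0 * (1.0 - dm.values)  # percent similarity
    pos = {s: k for k, s in enumerate(dm.ids)}
    group_of = {s: g for g, mem in members.items() for s in mem}

    rng = np.random.default_rng(seed)
    counts = {g: {h: 0 for h in labels} for g in labels}
    n_ties = 0
    audit_rows = []
    # sorted-id iteration makes the tie-break RNG stream order-independent
    for sid in sorted(group_of):
        g = group_of[sid]
        i = pos[sid]
        scores = {}
        for h in labels:
            others = [pos[s] for s in members[h] if s != sid]
            vals = sim[i, others]
            scores[h] = float(vals.mean()) if mode == "group_mean" else float(vals.max())
        best = max(scores.values())
        tied = sorted(h for h, v in scores.items() if np.isclose(v, best, rtol=0, atol=1e-12))
        if len(tied) > 1:
            n_ties += 1
            chosen = tied[int(rng.integers(len(tied)))]
        else:
            chosen = tied[0]
        counts[g][chosen] += 1
        audit_rows.append(
            {"strain_id": sid, "true_group": g, "assigned_group": chosen,
             "tie_flag": len(tied) > 1,
             **{f"sim_{h}": scores[h] for h in labels}}
        )

    k = len(labels)
    assignment = np.zeros((k, k))
    for a, g in enumerate(labels):
        for b, h in enumerate(labels):
            assignment[a, b] = 100.0 * counts[g][h] / len(members[g])

    avg_sim = np.zeros((k, k))
    for a, g in enumerate(labels):
        for b, h in enumerate(labels):
            if a == b:
                idx = [pos[s] for s in members[g]]
                iu, ju = np.triu_indices(len(idx), k=1)
                block = sim[np.ix_(idx, idx)]
                avg_sim[a, a] = float(block[iu, ju].mean())
            else:
                ia = [pos[s] for s in members[g]]
                ib = [pos[s] for s in members[h]]
                avg_sim[a, b] = float(sim[np.ix_(ia, ib)].mean())

    if cad_from == "similarity":
        cad = {g: 100.0 - avg_sim[a, a] for a, g in enumerate(labels)}
    else:
        cad = {g: 100.0 - assignment[a, a] for a, g in enumerate(labels)}

    return JKResult(
        groups=labels,
        assignment_pct=assignment,
        avg_similarity=avg_sim,
        cad=cad,
        n_ties=n_ties,
        seed=seed,
        locus_or_concat=locus_or_concat,
        audit=pd.DataFrame(audit_rows),
    )


def jk_report(results: Sequence[JKResult]) -> pd.DataFrame:
    """Long-format table over loci: one row per (locus, from_group, to_group)."""
    if not results:
        raise ValueError("no jackknife results to report")
    rows = []
    for res in results:
        for a, g in enumerate(res.groups):
            for b, h in enumerate(res.groups):
                rows.append(
                    {
                        "locus": res.locus_or_concat,
                        "from_group": g,
                        "to_group": h,
                        "assignment_pct": res.assignment_pct[a, b],
                        "avg_similarity": res.avg_similarity[a, b],
                        "cad": res.cad[g],
                    }
                )
    return pd.DataFrame(rows)
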