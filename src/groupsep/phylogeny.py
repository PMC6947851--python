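"""Neighbour-joining trees with nonparametric bootstrap supports.

The agglomeration is the Saitou–Nei algorithm with the standard
Q-criterion.  Ties in Q are broken deterministically on the
lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf id), so identical inputs always give the
same tree.  Negative branch-length estimates are clamped to zero with
the deficit moved to the sister branch; the raw estimates are kept in
an audit map.

Bootstrap supports resample alignment columns with replacement, rebuild
the tree per replicate, and report, for each internal edge of the
point-estimate tree, the fraction of replicates whose tree contains the
same bipartition of the leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .distances import DistanceError, DistanceMatrix, distance_matrix, encode_alignment
from .sequence_io import ConcatenateAlignment, LocusAlignment


@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths and optional edge supports."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)
    raw_branch_lengths: dict[str, float] = field(default_factory=dict)

    @property
    def leaf_ids(self) -> list[str]:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the frozenset of leaf ids on the
        side not containing the alphabetically first leaf."""
        return _bipartitions(self.tree)

    def path_distance(self, a: str, b: str) -> float:
        pdm = self.tree.phylogenetic_distance_matrix()
        tns = self.tree.taxon_namespace
        return pdm.patristic_distance(
            tns.get_taxon(a), tns.get_taxon(b)
        )


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    out: set[frozenset] = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.parent_node is None or node.is_leaf():
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if ref in side:
            side = set(leaves) - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset(side))
    return out


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Build the NJ tree for a distance matrix (n ≥ 3), unrooted."""
    n = dm.n
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(sorted(dm.ids))
    tree = dendropy.Tree(taxon_namespace=tns)
    # active clusters: label = smallest leaf id in cluster (for tie-breaks)
    order = sorted(dm.ids)
    D = dm.reorder(order).values.astype(float).copy()
    nodes: list[dendropy.Node] = []
    labels: list[str] = []
    for sid in order:
        node = dendropy.Node(taxon=tns.get_taxon(sid))
        nodes.append(node)
        labels.append(sid)
    raw: dict[str, float] = {}
    step = 0

    while len(nodes) > 3:
        step += 1
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # deterministic tie-break: smallest (label_i, label_j) pair
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((labels[i], labels[j]))), i, j)
            for i, j in cand if i < j
        )
        _, i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = D[i, j] - vi
        # clamp negatives, compensating the sister branch
        raw[f"{step}:{labels[i]}"] = vi
        raw[f"{step}:{labels[j]}"] = vj
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(vi, 0.0)
        nodes[j].edge.length = max(vj, 0.0)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        Dn = np.zeros((m - 1, m - 1))
        Dn[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        Dn[m - 2, : m - 2] = dnew[keep]
        Dn[: m - 2, m - 2] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
        D = Dn

    # final three-way join: three-point formulas
    a, b, c = 0, 1, 2
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, v in zip((a, b, c), (va, vb, vc)):
        raw[f"final:{labels[k]}"] = v
    root = dendropy.Node()
    for k, v in zip((a, b, c), (va, vb, vc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(v, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return PhyloTree(tree=tree, raw_branch_lengths=raw)


def bootstrap_support(
    aln: LocusAlignment | ConcatenateAlignment,
    model: str = "k2p",
    n_boot: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ point tree with column-bootstrap bipartition supports.

    Replicates whose resampled columns leave some pair with no
    comparable sites (or a saturated correction) are skipped and
    counted; more than 20% skipped is an error.
    """
    dm = distance_matrix(aln, model)
    point = neighbor_joining(dm)
    target = point.bipartitions()
    # a zero-signal alignment (all sequences identical) has an arbitrary
    # tie-break topology: report no supported bipartitions
    if not target or dm.values.max() == 0:
        point.supports = {}
        return point
    ids, X = encode_alignment(aln)
    L = X.shape[1]
    rng = np.random.default_rng(seed)
    counts = {bp: 0 for bp in target}
    skipped = 0
    done = 0
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        try:
            rep_dm = _matrix_from_encoded(ids, X[:, cols], model)
            rep_tree = neighbor_joining(rep_dm)
        except DistanceError:
            skipped += 1
            continue
        done += 1
        rep_bps = _bipartitions(rep_tree.tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if skipped > 0.2 * n_boot:
        raise DistanceError(
            f"bootstrap failed: {skipped}/{n_boot} replicates undefined"
        )
    point.supports = {bp: counts[bp] / done for bp in target}
    # annotate supports on internal nodes for Newick output
    leaves = sorted(ids)
    ref = leaves[0]
    for node in point.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if ref in side:
            side = set(leaves) - side
        bp = frozenset(side)
        if bp in point.supports:
            node.label = f"{point.supports[bp]:.3f}"
    return point


def _matrix_from_encoded(ids: list[str], X: np.ndarray, model: str) -> DistanceMatrix:
    """Distance matrix straight from an encoded (possibly resampled) alignment."""
    from .distances import _pairwise_counts, jc69_correct, k2p_correct

    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            nc, n_ts, n_tv = _pairwise_counts(X, i, j)
            if nc == 0:
                raise DistanceError("no comparable sites in replicate")
            p = (n_ts + n_tv) / nc
            if model == "p_distance":
                d = p
            elif model == "jc69":
                d = jc69_correct(p)
            else:
                d = k2p_correct(n_ts / nc, n_tv / nc)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids, vals, model)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Write Newick with branch lengths; supports as internal node labels."""
    s = tree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    Path(path).write_text(s)


def read_newick(path: str | Path) -> PhyloTree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def split_support(tree: PhyloTree, side: set[str]) -> float | None:
    """Support of the bipartition isolating ``side``, if present in the tree."""
    leaves = set(tree.leaf_ids)
    ref = sorted(leaves)[0]
    canon = frozenset(leaves - side if ref in side else side)
    return tree.supports.get(canon)
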