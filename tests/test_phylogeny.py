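import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groupsep import (
    DistanceMatrix,
    LocusAlignment,
    bootstrap_support,
    concatenate,
    groups_from_metadata,
    neighbor_joining,
    read_newick,
    split_support,
    write_newick,
)


def path_matrix(ptree, ids):
    pdm = ptree.tree.phylogenetic_distance_matrix()
    tns = ptree.tree.taxon_namespace
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tns.get_taxon(ids[i]), tns.get_taxon(ids[j]))
            out[i, j] = out[j, i] = d
    return out


def random_additive_matrix(rng, n):
    """Random binary tree with positive branch lengths -> additive matrix.

    Built by sequential leaf attachment; path lengths are the oracle.
    """
    import dendropy

    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    a = dendropy.Node(taxon=tns.get_taxon("t0"))
    b = dendropy.Node(taxon=tns.get_taxon("t1"))
    root.add_child(a)
    root.add_child(b)
    a.edge.length = rng.uniform(0.1, 2.0)
    b.edge.length = rng.uniform(0.1, 2.0)
    leaves = [a, b]
    for k in range(2, n):
        host = leaves[rng.integers(len(leaves))]
        new_internal = dendropy.Node()
        parent = host.parent_node
        elen = host.edge.length
        parent.remove_child(host)
        parent.add_child(new_internal)
        new_internal.edge.length = elen * 0.5
        new_internal.add_child(host)
        host.edge.length = elen * 0.5
        leaf = dendropy.Node(taxon=tns.get_taxon(f"t{k}"))
        new_internal.add_child(leaf)
        leaf.edge.length = rng.uniform(0.1, 2.0)
        leaves.append(leaf)
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    ids = [f"t{i}" for i in range(n)]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(
                tns.get_taxon(ids[i]), tns.get_taxon(ids[j])
            )
    from groupsep.phylogeny import _bipartitions

    return DistanceMatrix(ids, D, "p_distance"), _bipartitions(tree)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = neighbor_joining(DistanceMatrix(["A", "B", "C"], D, "p_distance"))
        P = path_matrix(t, ["A", "B", "C"])
        np.testing.assert_allclose(P, D, atol=1e-12)

    def test_four_taxon_worked_example(self):
        # additive matrix from ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = neighbor_joining(DistanceMatrix(ids, D, "p_distance"))
        assert t.bipartitions() == {frozenset({"C", "D"})}
        np.testing.assert_allclose(path_matrix(t, ids), D, atol=1e-9)

    @given(st.integers(0, 10_000), st.integers(4, 12))
    @settings(max_examples=20, deadline=None)
    def test_consistency_on_random_additive_matrices(self, seed, n):
        rng = np.random.default_rng(seed)
        dm, true_bps = random_additive_matrix(rng, n)
        t = neighbor_joining(dm)
        np.testing.assert_allclose(path_matrix(t, dm.ids), dm.values, atol=1e-9)
        assert t.bipartitions() == true_bps

    def test_matches_skbio_topology(self):
        skbio_tree = pytest.importorskip("skbio.tree")
        from skbio import DistanceMatrix as SkDM

        rng = np.random.default_rng(12)
        dm, _ = random_additive_matrix(rng, 8)
        mine = neighbor_joining(dm)
        sk = skbio_tree.nj(SkDM(dm.values, dm.ids))
        # compare bipartition sets
        leaves = sorted(dm.ids)
        ref = leaves[0]
        sk_bps = set()
        for node in sk.non_tips():
            side = {t.name for t in node.tips()}
            if ref in side:
                side = set(leaves) - side
            if 1 < len(side) < len(leaves) - 1:
                sk_bps.add(frozenset(side))
        assert mine.bipartitions() == sk_bps

    def test_all_equal_distances_deterministic(self):
        ids = [f"s{i}" for i in range(5)]
        D = np.ones((5, 5)) - np.eye(5)
        t1 = neighbor_joining(DistanceMatrix(ids, D, "p_distance"))
        t2 = neighbor_joining(DistanceMatrix(ids, D, "p_distance"))
        assert t1.tree.as_string(schema="newick") == t2.tree.as_string(schema="newick")

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]]), "p_distance")
            )

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(3)
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        t = neighbor_joining(DistanceMatrix([f"s{i}" for i in range(6)], m, "p_distance"))
        for edge in t.tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestBootstrapSupport:
    def test_separated_clades_fully_supported(self, separated_data, separated_groups):
        alns, _, _ = separated_data
        cc = concatenate([a for a in alns if a.category == "sym"], "sym")
        t = bootstrap_support(cc, model="k2p", n_boot=100, seed=2)
        for g, members in separated_groups.items():
            assert split_support(t, set(members)) >= 0.99

    def test_identical_sequences_no_supports(self):
        aln = LocusAlignment("flat", "hkg", {f"s{i}": "ACGT" * 20 for i in range(5)})
        t = bootstrap_support(aln, model="p_distance", n_boot=20, seed=0)
        assert t.supports == {}

    def test_same_seed_identical_supports(self, separated_data):
        alns, _, _ = separated_data
        t1 = bootstrap_support(alns[0], n_boot=50, seed=9)
        t2 = bootstrap_support(alns[0], n_boot=50, seed=9)
        assert t1.supports == t2.supports

    def test_supports_in_unit_interval_and_leaf_invariant(self, separated_data):
        alns, _, _ = separated_data
        t = bootstrap_support(alns[0], n_boot=50, seed=9)
        assert all(0 <= v <= 1 for v in t.supports.values())
        assert set(t.leaf_ids) == set(alns[0].strain_ids)


class TestNewickIO:
    def test_three_taxon_format(self, tmp_path):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = neighbor_joining(DistanceMatrix(["A", "B", "C"], D, "p_distance"))
        f = tmp_path / "t.nwk"
        write_newick(t, f)
        text = f.read_text()
        assert text.strip().endswith(";") and "A" in text

    def test_roundtrip_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(4)
        dm, _ = random_additive_matrix(rng, 7)
        t = neighbor_joining(dm)
        f = tmp_path / "t.nwk"
        write_newick(t, f)
        back = read_newick(f)
        assert back.bipartitions() == t.bipartitions()
        np.testing.assert_allclose(
            path_matrix(back, dm.ids), path_matrix(t, dm.ids), atol=1e-9
        )

    def test_supports_serialized_three_decimals(self, tmp_path, separated_data):
        alns, _, _ = separated_data
        t = bootstrap_support(alns[0], n_boot=40, seed=1)
        f = tmp_path / "s.nwk"
        write_newick(t, f)
        import re

        labels = re.findall(r"\)([01]\.\d{3}):", f.read_text())
        assert labels, "expected internal support labels"
        assert all(0 <= float(x) <= 1 for x in labels)
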