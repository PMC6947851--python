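import itertools

import numpy as np
import pytest

from groupsep import (
    DistanceError,
    LocusAlignment,
    compare_category_diversity,
    nst,
    nst_bootstrap,
    nucleotide_diversity,
    p_distance,
)

from conftest import random_alignment


def brute_force_nst(aln, groups, weighting="pair_weighted"):
    """Independent oracle: enumerate every pair explicitly."""
    members = {g: list(m) for g, m in groups.items()}
    pooled = [s for m in members.values() for s in m]
    all_pairs = list(itertools.combinations(pooled, 2))
    d = {frozenset(p): p_distance(aln.sequences[p[0]], aln.sequences[p[1]])[0]
         for p in all_pairs}
    R_t = np.mean([d[frozenset(p)] for p in all_pairs])
    within = {
        g: [d[frozenset(p)] for p in itertools.combinations(m, 2)]
        for g, m in members.items()
    }
    if weighting == "pair_weighted":
        flat = [v for vs in within.values() for v in vs]
        R_s = np.mean(flat)
    else:
        R_s = np.mean([np.mean(vs) for vs in within.values()])
    return R_t, R_s, (R_t - R_s) / R_t


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = LocusAlignment("x", "hkg", {f"s{i}": "AAAA" for i in range(3)})
        assert nucleotide_diversity(aln, ["s0", "s1", "s2"]).mean_pairwise_distance == 0.0

    def test_single_pair(self):
        aln = LocusAlignment("x", "hkg", {"a": "AAAA", "b": "AAAT"})
        res = nucleotide_diversity(aln, ["a", "b"])
        assert res.mean_pairwise_distance == 0.25
        assert res.n_pairs == 1

    def test_three_strains_hand_enumerated(self):
        # pairs: (AAAA,AAAT)=0.25, (AAAA,AATT)=0.5, (AAAT,AATT)=0.25
        aln = LocusAlignment("x", "hkg", {"a": "AAAA", "b": "AAAT", "c": "AATT"})
        res = nucleotide_diversity(aln, ["a", "b", "c"])
        assert res.mean_pairwise_distance == pytest.approx(1 / 3, abs=1e-12)
        assert res.n_pairs == 3

    def test_subset_too_small(self):
        aln = LocusAlignment("x", "hkg", {"a": "AAAA", "b": "AAAT"})
        with pytest.raises(ValueError):
            nucleotide_diversity(aln, ["a"])


class TestNst:
    def test_maximal_differentiation(self):
        aln = LocusAlignment(
            "x", "hkg",
            {"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTT"},
        )
        res = nst(aln, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert res.R_s == 0.0
        assert res.R_t == pytest.approx(4 / 6, abs=1e-12)
        assert res.N_st == 1.0

    def test_symmetric_split_null(self):
        # all 6 pairwise distances are 0.5 -> R_s = R_t -> N_st = 0
        aln = LocusAlignment(
            "x", "hkg",
            {"a1": "AAAT", "a2": "AATA", "b1": "ATAA", "b2": "TAAA"},
        )
        res = nst(aln, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert res.N_st == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_undefined(self):
        aln = LocusAlignment("x", "hkg", {f"s{i}": "ACGT" for i in range(4)})
        with pytest.raises(DistanceError, match="undefined"):
            nst(aln, {"A": ["s0", "s1"], "B": ["s2", "s3"]})

    def test_group_relabelling_invariance(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, n=8, length=40)
        ids = aln.strain_ids
        g1 = {"A": ids[:4], "B": ids[4:]}
        g2 = {"B": ids[4:], "A": ids[:4]}
        assert nst(aln, g1).N_st == pytest.approx(nst(aln, g2).N_st, abs=1e-15)

    def test_column_block_duplication_invariance(self):
        rng = np.random.default_rng(7)
        aln = random_alignment(rng, n=6, length=30)
        doubled = LocusAlignment(
            "dbl", "custom", {s: q + q for s, q in aln.sequences.items()}
        )
        ids = aln.strain_ids
        groups = {"A": ids[:3], "B": ids[3:]}
        assert nst(aln, groups).N_st == pytest.approx(
            nst(doubled, groups).N_st, abs=1e-12
        )

    @pytest.mark.parametrize("weighting", ["pair_weighted", "group_mean"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed, weighting):
        rng = np.random.default_rng(seed)
        aln = random_alignment(rng, n=8, length=25)
        ids = aln.strain_ids
        groups = {"A": ids[:3], "B": ids[3:]}  # unequal sizes on purpose
        res = nst(aln, groups, weighting=weighting)
        R_t, R_s, n_st = brute_force_nst(aln, groups, weighting)
        assert res.R_t == pytest.approx(R_t, abs=1e-12)
        assert res.R_s == pytest.approx(R_s, abs=1e-12)
        assert res.N_st == pytest.approx(n_st, abs=1e-12)

    def test_requires_two_groups_of_two(self):
        aln = LocusAlignment("x", "hkg", {"a": "AAAA", "b": "AAAT", "c": "ATTT"})
        with pytest.raises(ValueError):
            nst(aln, {"A": ["a"], "B": ["b", "c"]})


class TestNstBootstrap:
    def test_maximal_toy_all_replicates_one(self):
        aln = LocusAlignment(
            "x", "hkg",
            {"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTT"},
        )
        res = nst_bootstrap(
            aln, {"A": ["a1", "a2"], "B": ["b1", "b2"]}, n_boot=50, seed=9
        )
        assert res.ci95 == (1.0, 1.0)
        assert np.all(res.bootstrap_values == 1.0)
        assert res.n_undefined_reps == 0

    def test_deterministic_given_seed(self, separated_data, separated_groups):
        alns, _, _ = separated_data
        labels = list(separated_groups)
        groups = {l: separated_groups[l] for l in labels[:2]}
        r1 = nst_bootstrap(alns[0], groups, n_boot=60, seed=123)
        r2 = nst_bootstrap(alns[0], groups, n_boot=60, seed=123)
        np.testing.assert_array_equal(r1.bootstrap_values, r2.bootstrap_values)

    def test_ci_contains_point_estimate_on_simulated_data(
        self, separated_data, separated_groups
    ):
        alns, _, _ = separated_data
        labels = list(separated_groups)
        groups = {l: separated_groups[l] for l in labels[:2]}
        res = nst_bootstrap(alns[0], groups, n_boot=300, seed=4)
        assert res.ci95[0] <= res.N_st <= res.ci95[1]

    def test_undefined_replicates_counted_and_excluded(self):
        # one critical variable column: ~37% of column resamples miss it
        aln = LocusAlignment(
            "x", "hkg",
            {"a1": "TAAAA", "a2": "TAAAA", "b1": "AAAAA", "b2": "AAAAA"},
        )
        res = nst_bootstrap(aln, {"A": ["a1", "a2"], "B": ["b1", "b2"]},
                            n_boot=300, seed=1)
        assert 0 < res.n_undefined_reps < 150
        assert len(res.bootstrap_values) == 300 - res.n_undefined_reps

    def test_mostly_undefined_replicates_error(self):
        # gap structure makes every pair depend on a different single
        # column; a replicate is defined only if it samples all three
        # columns (P = 6/27), so most replicates are undefined
        aln = LocusAlignment(
            "x", "hkg",
            {"a1": "AC-", "a2": "-CA", "b1": "T-A", "b2": "-GT"},
        )
        with pytest.raises(DistanceError, match="too invariant|undefined"):
            nst_bootstrap(aln, {"A": ["a1", "a2"], "B": ["b1", "b2"]},
                          n_boot=200, seed=1)

    def test_strain_bootstrap_unit(self, separated_data, separated_groups):
        alns, _, _ = separated_data
        labels = list(separated_groups)
        groups = {l: separated_groups[l] for l in labels[:2]}
        res = nst_bootstrap(alns[0], groups, n_boot=100, seed=5, unit="strain")
        assert res.n_boot == 100 and len(res.bootstrap_values) > 0


class TestCategoryDiversityRatio:
    def _div(self, mean, k=4):
        from groupsep.differentiation import DiversityResult

        dm = np.full((k, k), mean)
        np.fill_diagonal(dm, 0.0)
        return DiversityResult("g", "l", mean, k * (k - 1) // 2,
                               [f"s{i}" for i in range(k)], dm)

    def test_identical_lists_ratio_one(self):
        h = [self._div(0.02), self._div(0.03)]
        s = [self._div(0.02), self._div(0.03)]
        ratio, ci = compare_category_diversity(h, s, n_boot=200, seed=0)
        assert ratio == pytest.approx(1.0)
        assert ci[0] <= 1.0 <= ci[1]

    def test_doubled_list_ratio_two(self):
        h = [self._div(0.01), self._div(0.02)]
        s = [self._div(0.02), self._div(0.04)]
        ratio, _ = compare_category_diversity(h, s, n_boot=100, seed=0)
        assert ratio == pytest.approx(2.0)

    def test_zero_hkg_diversity_errors(self):
        with pytest.raises(DistanceError, match="zero mean hkg"):
            compare_category_diversity([self._div(0.0)], [self._div(0.1)], 50, 0)

    def test_recovers_doubled_sym_rate(self):
        """sym mutation rate 2x hkg -> ratio CI should cover 2."""
        from groupsep import LocusSpec, SimConfig, groups_from_metadata, simulate

        cfg = SimConfig(
            n_groups=1, strains_per_group=[12],
            loci=[
                LocusSpec("h1", 900, "hkg", 1.0), LocusSpec("h2", 900, "hkg", 1.0),
                LocusSpec("s1", 900, "sym", 2.0), LocusSpec("s2", 900, "sym", 2.0),
            ],
            between_group_divergence=0.0, within_group_divergence=0.02,
            geography=[(43.0, 44.7, 10.0)], seed=21,
        )
        alns, meta, _ = simulate(cfg)
        mem = groups_from_metadata(meta)["G1"]
        h = [nucleotide_diversity(a, mem) for a in alns if a.category == "hkg"]
        s = [nucleotide_diversity(a, mem) for a in alns if a.category == "sym"]
        ratio, ci = compare_category_diversity(h, s, n_boot=400, seed=3)
        assert ci[0] <= 2.0 <= ci[1]
        assert ratio == pytest.approx(2.0, rel=0.25)
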