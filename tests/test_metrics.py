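import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from assemblage import synth
from assemblage.metrics import (
    beta_mntd,
    dissimilarity,
    faith_pd,
    generalized_unifrac,
    hill_beta_qd,
    hill_diversity,
    pairwise_dissimilarity,
)
from conftest import make_table


class TestTaxonomicDissimilarity:
    @pytest.mark.parametrize(
        "x, y, metric, expected",
        [
            ([1, 0, 1], [1, 1, 0], "jaccard", 2 / 3),
            ([3, 0, 1], [1, 2, 1], "ruzicka", 2 / 3),
            ([2, 2, 0], [0, 2, 2], "bray_curtis", 0.5),
            ([1, 2, 3], [1, 2, 3], "jaccard", 0.0),
            ([1, 2, 3], [2, 4, 6], "ruzicka", 0.5),
        ],
    )
    def test_hand_computed_values(self, x, y, metric, expected):
        d = pairwise_dissimilarity(np.array([x, y]), metric)
        assert d[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_scipy_bray_curtis(self):
        from scipy.spatial.distance import braycurtis

        rng = np.random.default_rng(0)
        x = rng.integers(0, 20, size=(6, 15))
        x[x.sum(axis=1) == 0, 0] = 1
        d = pairwise_dissimilarity(x, "bray_curtis")
        for i in range(6):
            for j in range(i + 1, 6):
                assert d[i, j] == pytest.approx(braycurtis(x[i], x[j]), abs=1e-10)

    @pytest.mark.parametrize("metric", ["jaccard", "ruzicka", "bray_curtis"])
    def test_disjoint_supports_give_one(self, metric):
        d = pairwise_dissimilarity(np.array([[3, 5, 0, 0], [0, 0, 2, 7]]), metric)
        assert d[0, 1] == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.integers(0, 50), min_size=4, max_size=4),
        st.lists(st.integers(0, 50), min_size=4, max_size=4),
    )
    def test_symmetry_range_zero_diagonal(self, x, y):
        m = np.array([x, y])
        if (m.sum(axis=1) == 0).any():
            return
        for metric in ("jaccard", "ruzicka", "bray_curtis"):
            d = pairwise_dissimilarity(m, metric)
            assert d[0, 1] == pytest.approx(d[1, 0])
            assert d[0, 0] == 0 == d[1, 1]
            assert -1e-12 <= d[0, 1] <= 1 + 1e-12

    def test_zero_total_sample_is_error(self):
        with pytest.raises(ValueError, match="zero total"):
            pairwise_dissimilarity(np.array([[1, 2], [0, 0]]), "bray_curtis")

    def test_dissimilarity_wraps_table(self, toy_table):
        pm = dissimilarity(toy_table, "ruzicka")
        assert pm.sample_ids == toy_table.sample_ids
        assert pm.values.to_numpy().diagonal().sum() == 0


class TestHillNumbers:
    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_uniform_community_gives_richness(self, q, n):
        assert hill_diversity(np.ones(n), q) == pytest.approx(n, abs=1e-9)

    def test_inverse_simpson_hand_value(self):
        assert hill_diversity([0.5, 0.25, 0.25], 2.0) == pytest.approx(1 / 0.375, abs=1e-10)

    def test_continuity_at_q_one(self):
        p = [0.6, 0.3, 0.08, 0.02]
        at1 = hill_diversity(p, 1.0)
        assert hill_diversity(p, 1.0 + 1e-4) == pytest.approx(at1, abs=1e-3)
        assert hill_diversity(p, 1.0 - 1e-4) == pytest.approx(at1, abs=1e-3)

    def test_negative_abundance_is_error(self):
        with pytest.raises(ValueError):
            hill_diversity([1, -1, 2], 1.0)


class TestHillBetaQd:
    @pytest.mark.parametrize("q", [0.0, 0.5, 1.0, 2.0])
    def test_identical_samples_give_zero(self, q):
        assert hill_beta_qd([3, 1, 2], [3, 1, 2], q) == pytest.approx(0.0, abs=1e-10)

    def test_disjoint_uniform_samples_give_one(self):
        assert hill_beta_qd([1, 1, 0, 0], [0, 0, 1, 1], 0.0) == pytest.approx(1.0, abs=1e-10)

    def test_one_shared_of_three_uniform(self):
        # gamma = 5 (taxa in union), alpha = 3 -> qd = 2/3
        qd = hill_beta_qd([1, 1, 1, 0, 0], [0, 0, 1, 1, 1], 0.0)
        assert qd == pytest.approx(2 / 3, abs=1e-10)

    @settings(derandomize=True, max_examples=25)
    @given(
        st.lists(st.integers(0, 30), min_size=5, max_size=5),
        st.lists(st.integers(0, 30), min_size=5, max_size=5),
        st.sampled_from([0.0, 0.5, 1.0, 2.0]),
        st.integers(2, 7),
    )
    def test_scale_and_relabeling_invariance(self, x, y, q, scale):
        x, y = np.array(x), np.array(y)
        if x.sum() == 0 or y.sum() == 0:
            return
        base = hill_beta_qd(x, y, q)
        assert 0.0 <= base <= 1.0
        assert hill_beta_qd(x * scale, y, q) == pytest.approx(base, abs=1e-9)
        perm = np.array([3, 1, 4, 0, 2])
        assert hill_beta_qd(x[perm], y[perm], q) == pytest.approx(base, abs=1e-9)


class TestFaithPD:
    @pytest.mark.parametrize(
        "taxa, expected",
        [({"A", "B", "C", "D"}, 6.0), ({"A", "B"}, 3.0), ({"A"}, 2.0), ({"A", "C"}, 4.0)],
    )
    def test_hand_computed_values(self, balanced_tree, taxa, expected):
        assert faith_pd(taxa, balanced_tree) == pytest.approx(expected, abs=1e-10)

    def test_unknown_tip_is_error(self, balanced_tree):
        with pytest.raises(KeyError):
            faith_pd({"A", "Z"}, balanced_tree)

    def test_agrees_with_skbio_on_random_sets(self):
        from skbio.diversity.alpha import faith_pd as skbio_faith

        tree = synth.generate_tree(25, seed=3)
        rng = np.random.default_rng(4)
        names = tree.tip_names
        for _ in range(10):
            k = rng.integers(1, 20)
            subset = list(rng.choice(names, size=k, replace=False))
            counts = [1 if n in subset else 0 for n in names]
            ref = skbio_faith(counts, taxa=names, tree=tree.tree)
            assert faith_pd(subset, tree) == pytest.approx(ref, abs=1e-10)


class TestBetaMNTD:
    def test_identical_single_taxon_samples(self, balanced_tree):
        assert beta_mntd([1, 0, 0, 0], [1, 0, 0, 0], balanced_tree) == 0.0

    def test_cross_cherry_singletons(self, balanced_tree):
        # patristic A-C distance = 4
        assert beta_mntd([1, 0, 0, 0], [0, 0, 1, 0], balanced_tree) == pytest.approx(4.0)

    def test_mixed_sample_hand_value(self, balanced_tree):
        # 0.5*0 + 0.5*(0.5*0 + 0.5*4) = 1
        assert beta_mntd([1, 0, 0, 0], [1, 0, 1, 0], balanced_tree) == pytest.approx(1.0)

    def test_matches_independent_reference_values(self, balanced_tree):
        # frozen from picante::comdistnt(abundance.weighted=TRUE) on this fixture
        comm = {"s1": [1, 0, 0, 0], "s2": [1, 0, 1, 0], "s3": [0, 2, 1, 3]}
        expected = {("s1", "s2"): 1.0, ("s1", "s3"): 8 / 3, ("s2", "s3"): 4 / 3}
        for (a, b), ref in expected.items():
            assert beta_mntd(comm[a], comm[b], balanced_tree) == pytest.approx(ref, abs=1e-10)

    def test_pair_order_invariance(self, balanced_tree):
        x, y = [3, 1, 0, 2], [0, 2, 5, 1]
        assert beta_mntd(x, y, balanced_tree) == pytest.approx(beta_mntd(y, x, balanced_tree))


class TestGeneralizedUnifrac:
    def test_identical_samples_give_zero(self, balanced_tree):
        assert generalized_unifrac([1, 2, 3, 4], [1, 2, 3, 4], balanced_tree) == pytest.approx(0.0)

    def test_disjoint_cherries_give_one(self, balanced_tree):
        assert generalized_unifrac([2, 1, 0, 0], [0, 0, 1, 3], balanced_tree) == pytest.approx(1.0)

    def test_alpha_one_matches_skbio_weighted_normalized(self):
        from skbio.diversity.beta import weighted_unifrac

        tree = synth.generate_tree(20, seed=7)
        rng = np.random.default_rng(8)
        names = tree.tip_names
        for _ in range(10):
            x = rng.integers(0, 30, size=20)
            y = rng.integers(0, 30, size=20)
            if x.sum() == 0 or y.sum() == 0:
                continue
            ref = weighted_unifrac(x, y, taxa=names, tree=tree.tree, normalized=True)
            mine = generalized_unifrac(x, y, tree, alpha=1.0)
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_alpha_out_of_range_is_error(self, balanced_tree):
        with pytest.raises(ValueError):
            generalized_unifrac([1, 0, 0, 0], [0, 1, 0, 0], balanced_tree, alpha=1.5)
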