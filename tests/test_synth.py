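import numpy as np
import pytest

from assemblage import synth
from assemblage.io import harmonize
from assemblage.metrics import pairwise_dissimilarity


class TestGenerateTree:
    def test_two_taxa_cherry_is_ultrametric(self):
        tree = synth.generate_tree(2, seed=0)
        labels, d = tree.patristic()
        # both root-to-tip paths equal -> patristic distance = 2 * height
        a = tree.tip_path_edges(labels[0])
        b = tree.tip_path_edges(labels[1])
        assert tree._length[a].sum() == pytest.approx(tree._length[b].sum())

    def test_fixed_seed_reproduces_newick(self):
        t1 = synth.generate_tree(50, seed=9)
        t2 = synth.generate_tree(50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_ultrametric_three_point_condition(self):
        tree = synth.generate_tree(50, seed=9)
        labels, d = tree.patristic()
        rng = np.random.default_rng(1)
        for _ in range(200):
            i, j, k = rng.choice(len(labels), size=3, replace=False)
            two_largest = sorted([d[i, j], d[i, k], d[j, k]])[1:]
            assert two_largest[0] == pytest.approx(two_largest[1], rel=1e-9)

    def test_too_few_taxa_is_error(self):
        with pytest.raises(ValueError):
            synth.generate_tree(1, seed=0)


class TestRegimeDatasets:
    def test_generated_dataset_passes_validation(self):
        tree = synth.generate_tree(30, seed=2)
        for regime in ("neutral", "homogeneous_selection", "variable_selection",
                       "dispersal_limited", "lottery"):
            ds, truth = synth.generate_regime_dataset(tree, regime, 5, 2000, seed=3)
            assert ds.table.n_samples == 5
            assert set(ds.tree.tip_names) == set(ds.table.asv_ids)
            assert truth.regime == regime
            again = harmonize(ds.table, ds.tree)
            assert again.table.counts.equals(ds.table.counts)

    def test_fixed_seed_reproduces_counts(self):
        tree = synth.generate_tree(30, seed=2)
        a, _ = synth.generate_regime_dataset(tree, "variable_selection", 6, 1000, seed=7)
        b, _ = synth.generate_regime_dataset(tree, "variable_selection", 6, 1000, seed=7)
        assert a.table.counts.equals(b.table.counts)

    def test_neutral_bray_curtis_decreases_with_depth(self):
        # multinomial sampling noise shrinks with depth, so expected
        # between-replicate dissimilarity decreases toward 0
        tree = synth.generate_tree(30, seed=2)
        means = []
        for depth in (100, 1000, 10_000):
            vals = []
            for s in range(8):
                ds, _ = synth.generate_regime_dataset(tree, "neutral", 2, depth, seed=100 + s)
                vals.append(pairwise_dissimilarity(ds.table.counts.to_numpy(), "bray_curtis")[0, 1])
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_lottery_winner_share_dominates_groups(self):
        tree = synth.generate_tree(40, seed=5)
        ds, truth = synth.generate_regime_dataset(
            tree, "lottery", 8, 20_000, seed=6, winner_fraction=0.95
        )
        genera = ds.table.genera()
        counts = ds.table.counts
        checked = 0
        for genus in truth.parameters["lottery_genera"]:
            members = genera.index[genera == genus]
            sub = counts[members]
            totals = sub.sum(axis=1)
            shares = sub.max(axis=1)[totals >= 200] / totals[totals >= 200]
            checked += len(shares)
            assert (shares >= 0.95 - 0.05).all()
        assert checked > 0

    def test_infinitely_narrow_niche_single_winner(self):
        tree = synth.generate_tree(30, seed=2)
        ds, truth = synth.generate_regime_dataset(
            tree, "homogeneous_selection", 5, 5000, seed=3, niche_width=1e-4
        )
        rel = ds.table.counts.to_numpy() / 5000
        assert (rel.max(axis=1) > 0.99).all()
        assert len(set(rel.argmax(axis=1))) == 1

    def test_invalid_sizes_are_errors(self):
        tree = synth.generate_tree(10, seed=2)
        with pytest.raises(ValueError):
            synth.generate_regime_dataset(tree, "neutral", 1, 100, seed=0)
        with pytest.raises(ValueError):
            synth.generate_regime_dataset(tree, "neutral", 3, 0, seed=0)


class TestTimeSeries:
    def test_fixed_seed_reproduces_detection_order(self):
        tree = synth.generate_tree(40, seed=8)
        _, t1 = synth.generate_time_series(tree, 1.5, 5, 5, seed=4)
        _, t2 = synth.generate_time_series(tree, 1.5, 5, 5, seed=4)
        assert t1.parameters["recruitment_order"] == t2.parameters["recruitment_order"]

    def test_overdispersed_pd_curve_dominates_underdispersed(self):
        from assemblage.metrics import faith_pd

        tree = synth.generate_tree(60, seed=8)
        curves = {}
        for d_true in (5.0, -5.0):
            acc = np.zeros(5)
            for s in range(15):
                _, truth = synth.generate_time_series(tree, d_true, 5, 8, seed=700 + s)
                detected = list(truth.parameters["initial"])
                order = truth.parameters["recruitment_order"]
                for k in range(5):
                    if k > 0:
                        detected += order[(k - 1) * 8 : k * 8]
                    acc[k] += faith_pd(detected, tree)
            curves[d_true] = acc / 15
        assert (curves[5.0][1:] > curves[-5.0][1:]).all()

    def test_neutral_recruitment_is_uniform(self):
        tree = synth.generate_tree(12, seed=8)
        rng = np.random.default_rng(0)
        first = []
        initial = tree.tip_names[:2]
        for _ in range(600):
            order = synth.recruitment_order(tree, 0.0, 1, initial, rng)
            first.append(order[0])
        freq = np.array([first.count(t) for t in tree.tip_names[2:]])
        expected = 600 / 10
        assert (np.abs(freq - expected) < 5 * np.sqrt(expected)).all()

    def test_too_many_recruits_is_error(self):
        tree = synth.generate_tree(10, seed=8)
        with pytest.raises(ValueError):
            synth.generate_time_series(tree, 0.0, 5, 5, seed=0)

    def test_day_grid_mirrors_study(self):
        tree = synth.generate_tree(40, seed=8)
        ds, _ = synth.generate_time_series(tree, 0.0, 5, 3, seed=4)
        assert sorted(ds.table.metadata["day"]) == [0, 3, 7, 14, 28]


class TestStudyDesign:
    def test_layout_and_determinism(self):
        ds, truths = synth.study_design(seed=3, n_taxa=40, depth=1000)
        meta = ds.table.metadata
        assert sorted(meta["group"].unique()) == sorted(synth.DEFAULT_GROUPS)
        assert sorted(meta["day"].unique()) == [0, 3, 7, 14, 28]
        assert ds.table.n_samples == 7 * 5 * 3
        assert set(truths) == set(synth.DEFAULT_GROUPS)
        ds2, _ = synth.study_design(seed=3, n_taxa=40, depth=1000)
        assert ds.table.counts.equals(ds2.table.counts)
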