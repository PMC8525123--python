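import numpy as np
import pandas as pd
import pytest

from assemblage import synth
from assemblage.io import CommunityTable, harmonize, parse_newick
from assemblage.metrics import faith_pd
from assemblage.phylodisp import fit_dispersion, pd_accumulation, surrogate_null


def _staggered_dataset(newick, appearances, days):
    """One sample per day; taxon j appears from appearances[j] onward."""
    tree = parse_newick(newick)
    names = tree.tip_names
    rows, ids, meta = [], [], []
    for k, d in enumerate(days):
        row = [10 if appearances[names[j]] <= k else 0 for j in range(len(names))]
        rows.append(row)
        ids.append(f"G_d{d}")
        meta.append({"group": "G", "day": d, "replicate": 1})
    table = CommunityTable(
        pd.DataFrame(rows, index=ids, columns=names),
        pd.DataFrame(meta, index=ids),
        pd.Series([f"d;p;c;o;f;g_{n};s" for n in names], index=names),
    )
    return harmonize(table, tree)


class TestPdAccumulation:
    def test_all_present_at_day_zero_is_flat(self):
        tree = synth.generate_tree(15, seed=1)
        ds = _staggered_dataset(
            tree.to_newick(), {n: 0 for n in tree.tip_names}, [0, 3, 7]
        )
        acc = pd_accumulation(ds, "G")
        total = faith_pd(ds.tree.tip_names, ds.tree)
        assert np.allclose(acc["pd"], total)

    def test_star_tree_adds_one_tip_path_per_day(self):
        newick = "(A:1,B:1,C:1,D:1,E:1);"
        appearances = {"A": 0, "B": 0, "C": 1, "D": 2, "E": 3}
        ds = _staggered_dataset(newick, appearances, [0, 3, 7, 14])
        acc = pd_accumulation(ds, "G")
        assert acc["pd"].tolist() == [2.0, 3.0, 4.0, 5.0]
        assert acc["n_detected"].tolist() == [2, 3, 4, 5]

    def test_monotone_non_decreasing(self):
        tree = synth.generate_tree(40, seed=2)
        ds, _ = synth.generate_time_series(tree, -2.0, 5, 6, seed=3)
        acc = pd_accumulation(ds, "SYN")
        assert (np.diff(acc["pd"]) >= -1e-12).all()

    def test_single_time_point_is_error(self):
        tree = synth.generate_tree(10, seed=1)
        ds = _staggered_dataset(tree.to_newick(), {n: 0 for n in tree.tip_names}, [0, 3])
        with pytest.raises(ValueError, match="time points"):
            pd_accumulation(ds, "G")


class TestSurrogateNull:
    def test_fixed_seed_is_bit_reproducible(self):
        tree = synth.generate_tree(30, seed=4)
        ds, _ = synth.generate_time_series(tree, 0.0, 5, 4, seed=5)
        a = surrogate_null(ds, "SYN", n_surrogates=50, seed=9)
        b = surrogate_null(ds, "SYN", n_surrogates=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_final_day_matches_observed_when_pool_exhausted(self):
        # every pool taxon is detected by the final day, so all surrogates
        # end at the observed final PD
        tree = synth.generate_tree(12, seed=6)
        names = tree.tip_names
        appearances = {n: min(i // 4, 2) for i, n in enumerate(names)}
        ds = _staggered_dataset(tree.to_newick(), appearances, [0, 3, 7])
        null = surrogate_null(ds, "G", n_surrogates=40, seed=1)
        obs = pd_accumulation(ds, "G")
        assert null["null_mean"].iloc[-1] == pytest.approx(obs["pd"].iloc[-1])
        assert null["null_sd"].iloc[-1] == pytest.approx(0.0, abs=1e-12)

    def test_null_brackets_observed_curve_under_neutrality(self):
        tree = synth.generate_tree(50, seed=7)
        ds, _ = synth.generate_time_series(tree, 0.0, 5, 6, seed=8)
        null = surrogate_null(ds, "SYN", n_surrogates=100, seed=2)
        obs = pd_accumulation(ds, "SYN")
        inside = (
            (obs["pd"] >= null["null_q025"] - 1e-9)
            & (obs["pd"] <= null["null_q975"] + 1e-9)
        )
        assert inside.mean() >= 0.8


class TestFitDispersion:
    def test_sign_recovery_both_directions(self):
        tree = synth.generate_tree(80, seed=21)
        ds_pos, _ = synth.generate_time_series(tree, 3.0, 5, 10, seed=210)
        ds_neg, _ = synth.generate_time_series(tree, -3.0, 5, 10, seed=210)
        fit_pos = fit_dispersion(ds_pos, "SYN", n_surrogates=60, n_bootstrap=50, seed=5)
        fit_neg = fit_dispersion(ds_neg, "SYN", n_surrogates=60, n_bootstrap=50, seed=5)
        assert fit_pos.d_hat > 0 > fit_neg.d_hat
        assert fit_pos.converged and fit_neg.converged

    def test_fitted_model_beats_neutral_when_d_large(self):
        tree = synth.generate_tree(80, seed=21)
        ds, _ = synth.generate_time_series(tree, 3.0, 5, 10, seed=211)
        fit = fit_dispersion(ds, "SYN", n_surrogates=60, n_bootstrap=50, seed=5)
        sse = fit.sse_by_d.set_index("d")["sse"]
        q25, q75 = np.quantile(fit.bootstrap_distribution, [0.25, 0.75])
        if abs(fit.d_hat) > q75 - q25:
            neutral_sse = ((fit.null_mean_pd - fit.observed_pd) ** 2).sum()
            assert sse.min() < neutral_sse

    def test_bootstrap_length_and_determinism(self):
        tree = synth.generate_tree(40, seed=22)
        ds, _ = synth.generate_time_series(tree, 0.0, 4, 5, seed=23)
        a = fit_dispersion(ds, "SYN", n_surrogates=30, n_bootstrap=40, seed=6)
        b = fit_dispersion(ds, "SYN", n_surrogates=30, n_bootstrap=40, seed=6)
        assert len(a.bootstrap_distribution) == 40
        assert a.d_hat == b.d_hat
        assert np.array_equal(a.bootstrap_distribution, b.bootstrap_distribution)

    def test_no_recruitment_is_error(self):
        tree = synth.generate_tree(10, seed=1)
        ds = _staggered_dataset(tree.to_newick(), {n: 0 for n in tree.tip_names}, [0, 3, 7])
        with pytest.raises(ValueError, match="recruits"):
            fit_dispersion(ds, "G", n_surrogates=10, n_bootstrap=10, seed=0)
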