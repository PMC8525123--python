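import numpy as np
import pandas as pd
import pytest

from assemblage import synth
from assemblage.io import CommunityTable, harmonize
from assemblage.qpe import (
    PROCESSES,
    ProcessProfile,
    beta_nti,
    beta_nti_matrix,
    classify_processes,
    rc_bray,
)
from conftest import make_table


def _dataset(regime="neutral", n_samples=6, seed=3, n_taxa=40, depth=500, **kw):
    # sparse supports (heavy-tailed SAD, modest depth) keep the
    # taxa-shuffle null non-degenerate on this small fixture
    kw.setdefault("sad_sigma", 2.0)
    tree = synth.generate_tree(n_taxa, seed=seed)
    ds, _ = synth.generate_regime_dataset(tree, regime, n_samples, depth, seed=seed + 1, **kw)
    return ds


class TestBetaNTI:
    def test_pair_order_invariance(self):
        ds = _dataset()
        a = beta_nti(ds, ("SYN_d0_r1", "SYN_d0_r2"), n_rand=99, seed=1)
        b = beta_nti(ds, ("SYN_d0_r2", "SYN_d0_r1"), n_rand=99, seed=1)
        assert a == pytest.approx(b, abs=1e-12)

    def test_identical_samples_are_degenerate(self):
        # identical supports give zero βMNTD under every label permutation,
        # so the null collapses and the pair is flagged, not scored
        ds = _dataset()
        counts = ds.table.counts.copy()
        counts.iloc[1] = counts.iloc[0]
        table = CommunityTable(counts, ds.table.metadata, ds.table.taxonomy)
        ds2 = harmonize(table, ds.tree)
        with pytest.raises(ValueError, match="degenerate"):
            beta_nti_matrix(ds2, pairs=[("SYN_d0_r1", "SYN_d0_r2")], n_rand=99, seed=1)

    def test_clustered_unshared_taxa_give_negative_score(self):
        # the unshared taxon of each sample is the sister of a taxon the
        # other sample holds, so observed nearest-taxon turnover is tiny
        ds = _dataset()
        labels, dmat = ds.tree.patristic()
        np.fill_diagonal(dmat, np.inf)
        i, j = np.unravel_index(np.argmin(dmat), dmat.shape)  # closest cherry
        u, v = labels[i], labels[j]
        counts = ds.table.counts.copy()
        counts.iloc[1] = counts.iloc[0]
        s1, s2 = counts.index[:2]
        counts.loc[s1, [u, v]] = [40, 0]
        counts.loc[s2, [u, v]] = [0, 40]
        table = CommunityTable(counts, ds.table.metadata, ds.table.taxonomy)
        ds2 = harmonize(table, ds.tree)
        df = beta_nti_matrix(ds2, pairs=[("SYN_d0_r1", "SYN_d0_r2")], n_rand=199, seed=1)
        assert df["beta_nti"].iloc[0] < -1

    def test_shared_null_ensemble_consistent_with_single_pair(self):
        ds = _dataset()
        pair = ("SYN_d0_r1", "SYN_d0_r3")
        single = beta_nti(ds, pair, n_rand=199, seed=4)
        multi = beta_nti_matrix(ds, n_rand=199, seed=4)
        row = multi[(multi.sample_a == pair[0]) & (multi.sample_b == pair[1])]
        assert single == pytest.approx(float(row["beta_nti"].iloc[0]), abs=1e-12)

    def test_too_few_randomizations_is_error(self):
        ds = _dataset()
        with pytest.raises(ValueError):
            beta_nti(ds, ("SYN_d0_r1", "SYN_d0_r2"), n_rand=10, seed=0)


class TestRcBray:
    def test_identical_samples_give_minus_one(self):
        counts = [[5, 3, 2, 1, 4], [5, 3, 2, 1, 4], [1, 1, 8, 2, 3]]
        table = make_table(counts)
        assert rc_bray(table, ("s1", "s2"), n_rand=99, seed=0) == pytest.approx(-1.0)

    def test_disjoint_pair_at_upper_boundary(self):
        # observed Bray-Curtis is 1 >= every null draw; occasional null
        # draws that are also disjoint count as half (tie handling)
        counts = [[10, 10, 10, 0, 0, 0], [0, 0, 0, 10, 10, 10], [5, 5, 5, 5, 5, 5]]
        table = make_table(counts)
        rc = rc_bray(table, ("s1", "s2"), n_rand=199, seed=0)
        assert 0.9 < rc <= 1.0

    def test_scaling_maps_to_unit_interval(self):
        ds = _dataset()
        rc = rc_bray(ds.table, ("SYN_d0_r1", "SYN_d0_r2"), n_rand=99, seed=1)
        assert -1.0 <= rc <= 1.0


class TestClassifyProcesses:
    def test_fractions_sum_to_one(self):
        ds = _dataset()
        profile, pairs = classify_processes(ds, n_rand=99, seed=2)
        assert sum(profile.fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert set(pairs["process"]) <= set(PROCESSES)
        assert profile.n_pairs == len(pairs)

    def test_profile_validates_fractions(self):
        with pytest.raises(ValueError):
            ProcessProfile("g", {p: 0.5 for p in PROCESSES}, n_pairs=4)

    def test_homogeneous_selection_recovered(self):
        tree = synth.generate_tree(400, seed=11)
        ds, _ = synth.generate_regime_dataset(
            tree, "homogeneous_selection", 9, 500, seed=101,
            sad_sigma=0.5, niche_width=0.3, occupancy=0.5, trait_delta=0.3,
        )
        profile, _ = classify_processes(ds, n_rand=99, seed=5)
        assert profile.modal == "homogeneous_selection"

    def test_dispersal_limited_recovered_as_modal(self):
        tree = synth.generate_tree(400, seed=11)
        ds, _ = synth.generate_regime_dataset(
            tree, "dispersal_limited", 9, 1000, seed=1,
            sad_sigma=0.5, n_clades=400, clade_fraction=0.25,
        )
        profile, _ = classify_processes(ds, n_rand=99, seed=5)
        assert profile.modal == "dispersal_limitation"
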