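"""Accuracy and reproducibility statistics: AUC against brute-force pair
counting, selection profiles, and the psi summary statistics with their
sampling-oracle equivalence."""
import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import repromap as rm
from repromap.metrics import (auc, psi_sp, psi_z, selection_profile,
                              summarize_grid)


def brute_force_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == 0.75

    def test_label_flip_symmetry(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        assert auc(s, y) == pytest.approx(1 - auc(s, 1 - y), abs=1e-12)

    def test_ties_count_half(self):
        assert auc([1.0, 1.0], [1, 0]) == 0.5

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 10), min_size=2, max_size=50),
           st.data())
    def test_matches_brute_force_pair_counting(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        got = auc(np.array(scores, float), np.array(labels))
        assert got == pytest.approx(brute_force_auc(scores, labels),
                                    abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestSelectionProfile:
    def test_single_map_probabilities_are_binary(self):
        prof = selection_profile([np.array([0.0, 1.5, 0.0, -2.0])])
        assert set(np.unique(prof.v)) <= {0.0, 1.0}
        assert prof.B == 1

    def test_counts_from_two_sparse_maps(self):
        maps = [(np.array([0, 1]), np.array([1.0, 2.0])),
                (np.array([1, 2]), np.array([3.0, 4.0]))]
        prof = selection_profile(maps, n_voxels=3)
        np.testing.assert_allclose(prof.v, [0.5, 1.0, 0.5])
        np.testing.assert_allclose(prof.mu, [0.5, 2.5, 2.0])

    def test_dense_and_sparse_inputs_agree(self, rng):
        W = rng.normal(size=(6, 10)) * (rng.random((6, 10)) < 0.4)
        dense = selection_profile(list(W))
        sparse = selection_profile(
            [(np.flatnonzero(row), row[np.flatnonzero(row)]) for row in W],
            n_voxels=10)
        np.testing.assert_allclose(dense.v, sparse.v)
        np.testing.assert_allclose(dense.mu, sparse.mu)
        np.testing.assert_allclose(dense.se, sparse.se, atol=1e-12)

    def test_se_is_sample_sd_over_all_maps_with_zeros(self, rng):
        W = rng.normal(size=(5, 4)) * (rng.random((5, 4)) < 0.5)
        prof = selection_profile(list(W))
        np.testing.assert_allclose(prof.se, W.std(axis=0, ddof=1),
                                   atol=1e-12)
        np.testing.assert_allclose(prof.mu, W.mean(axis=0))

    def test_constant_nonzero_weight_gives_infinite_z(self):
        maps = [np.array([2.0, 0.0])] * 3
        prof = selection_profile(maps)
        assert prof.se[0] == 0 and np.isinf(prof.z[0]) and prof.z[0] > 0
        assert prof.z[1] == 0


def two_stage_oracle(maps, n_voxels):
    """Pick a map uniformly, pick a selected voxel uniformly, average its
    selection probability (exhaustive enumeration)."""
    B = len(maps)
    count = np.zeros(n_voxels)
    for idx in maps:
        count[idx] += 1
    v = count / B
    total, weight = 0.0, 0
    for idx in maps:
        for i in idx:
            total += v[i] / len(idx)
            weight += 1
    return total / B if weight else np.nan


class TestPsiSp:
    def test_perfect_reliability_gives_one(self):
        prof = selection_profile([np.array([1.0, 0.0, 2.0])] * 4)
        assert psi_sp(prof) == 1.0

    def test_weighted_example(self):
        maps = [(np.array([0, 1]), np.ones(2)),
                (np.array([1, 2]), np.ones(2))]
        prof = selection_profile(maps, n_voxels=3)
        assert psi_sp(prof) == pytest.approx(0.75)

    def test_disjoint_singleton_supports_give_one_over_B(self):
        for B in (2, 3, 5):
            maps = [(np.array([i]), np.array([1.0])) for i in range(B)]
            prof = selection_profile(maps, n_voxels=B)
            assert psi_sp(prof) == pytest.approx(1.0 / B)

    def test_matches_two_stage_sampling_oracle_exhaustively(self):
        # all multisets of equal-size supports, B <= 4 maps over p <= 6
        p = 6
        for support_size in (1, 2, 3):
            supports = list(itertools.combinations(range(p), support_size))
            for B in (1, 2, 3):
                for chosen in itertools.combinations_with_replacement(
                        supports, B):
                    maps = [(np.array(s), np.ones(support_size))
                            for s in chosen]
                    prof = selection_profile(maps, n_voxels=p)
                    assert psi_sp(prof) == pytest.approx(
                        two_stage_oracle([np.array(s) for s in chosen], p),
                        abs=1e-12)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 7), min_size=0, max_size=8),
                    min_size=1, max_size=6))
    def test_bounds_and_perfect_reliability_equivalence(self, raw_maps):
        maps = [(np.unique(np.array(m, dtype=int)), None) for m in raw_maps]
        maps = [(idx, np.ones(idx.size)) for idx, _ in maps]
        if not any(idx.size for idx, _ in maps):
            return
        prof = selection_profile(maps, n_voxels=8)
        val = psi_sp(prof)
        assert 0 < val <= 1 + 1e-12
        binary = np.all(np.isin(prof.v, [0.0, 1.0]))
        assert (val == pytest.approx(1.0)) == bool(binary)

    def test_all_zero_profile_rejected(self):
        prof = selection_profile([np.zeros(3)])
        with pytest.raises(ValueError):
            psi_sp(prof)


class TestPsiZ:
    def test_equal_z_scores_give_their_magnitude(self, rng):
        W = np.stack([np.array([1.0, -1.0]) + 0.1 * rng.normal(size=2)
                      for _ in range(20)])
        prof = selection_profile(list(W))
        expect = np.abs(prof.z)
        assert psi_z(prof) == pytest.approx(
            (prof.v * expect).sum() / prof.v.sum())

    def test_weighted_example(self):
        prof = rm.SelectionProfile(
            v=np.array([0.5, 1.0, 0.5]), mu=np.ones(3),
            se=np.ones(3), z=np.array([2.0, 4.0, 2.0]), B=2)
        assert psi_z(prof) == pytest.approx(3.0)

    def test_sign_flip_invariance(self, rng):
        W = rng.normal(size=(8, 5)) * (rng.random((8, 5)) < 0.6)
        a = psi_z(selection_profile(list(W)))
        b = psi_z(selection_profile(list(-W)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_infinite_sentinels_excluded_with_warning(self):
        maps = [np.array([2.0, 1.0]), np.array([2.0, 3.0])]
        prof = selection_profile(maps)
        with pytest.warns(UserWarning, match="zero weight"):
            val = psi_z(prof)
        assert val == pytest.approx(np.abs(prof.z[1]))

    def test_propagate_mode_returns_inf(self):
        prof = selection_profile([np.array([2.0]), np.array([2.0])])
        assert psi_z(prof, on_infinite="propagate") == np.inf


class TestSummarizeGrid:
    def test_separable_data_reaches_perfect_accuracy(self, medium_run):
        summ = medium_run["summary"]
        assert np.nanmax(summ.Az[summ.eligible]) > 0.95

    def test_summary_ranges(self, medium_run):
        summ = medium_run["summary"]
        ok = summ.eligible
        assert np.all((summ.Az[ok] >= 0) & (summ.Az[ok] <= 1))
        assert np.all((summ.psi_sp[ok] > 0) & (summ.psi_sp[ok] <= 1))
        assert np.all(summ.psi_z[ok][~np.isnan(summ.psi_z[ok])] >= 0)
        assert np.all(summ.n_bar[ok] >= 0)

    def test_psi_measures_strongly_correlated(self):
        # the two reproducibility statistics should track each other across
        # the grid when models range from weak to strong; a weak-signal run
        # spans that range
        spec = rm.SyntheticSpec(n_trials=150, n_voxels=500,
                                grid_shape=(10, 10, 5), n_signal_voxels=25,
                                n_signal_clusters=3, effect_size=0.5, seed=7)
        ds, _ = rm.make_trial_dataset(spec)
        grid = rm.default_grid(ds.X, ds.y, n_lambda1=8, n_lambda2=5,
                               lambda1_ratio=0.05)
        plan = rm.make_cv_plan(ds.n_trials, 10, 2, seed=7, y=ds.y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = summarize_grid(
                rm.fit_grid_family(ds.X, ds.y, grid, plan, max_voxels=400))
        ok = summ.eligible & np.isfinite(summ.psi_z)
        r = np.corrcoef(summ.psi_sp[ok], summ.psi_z[ok])[0, 1]
        assert r > 0.8

    def test_single_map_family_is_degenerate_but_defined(self, rng):
        X = rng.normal(size=(40, 12))
        y = (np.arange(40) % 4 == 0).astype(int)
        grid = rm.RegGrid(lambda2_values=np.array([1.0]),
                          lambda1_paths=np.array([[1.5]]))
        plan = rm.make_cv_plan(40, 4, 1, seed=0, y=y)
        fam = rm.fit_grid_family(X, y, grid, plan)
        prof = fam.selection_profile(0)
        if prof.n_bar > 0 and prof.B == 1:
            assert psi_sp(prof) == 1.0

    def test_roundtrip_through_frame(self, medium_run):
        summ = medium_run["summary"]
        back = rm.GridSummary.from_frame(summ.to_frame())
        np.testing.assert_allclose(back.Az, summ.Az)
        np.testing.assert_array_equal(back.capped, summ.capped)
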