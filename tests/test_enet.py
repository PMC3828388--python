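"""Elastic-net logistic solver: objective identities, KKT optimality,
warm-start consistency and the voxel cap."""
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import repromap as rm
from repromap.enet import (ConvergenceError, RegGrid, enet_objective,
                           fit_enet, fit_grid_family, lambda_max)


def _logistic_data(rng, n=100, p=20, k=3):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[:k] = rng.normal(size=k) + np.sign(rng.normal(size=k))
    y = (rng.random(n) < expit(X @ beta)).astype(int)
    if np.unique(y).size < 2:
        y[0] = 1 - y[0]
    return X, y


def _standardized(X):
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (X - X.mean(axis=0)) / sd


class TestObjective:
    def test_zero_model_balanced_labels_gives_n_log2(self, rng):
        n, p = 12, 4
        X = rng.normal(size=(n, p))
        y = np.arange(n) % 2
        assert enet_objective(np.zeros(p), 0.0, X, y, 0.0, 0.0) == \
            pytest.approx(n * np.log(2), rel=1e-12)

    def test_penalty_of_zero_vector_is_zero(self, rng):
        n, p = 10, 3
        X = rng.normal(size=(n, p))
        y = np.arange(n) % 2
        base = enet_objective(np.zeros(p), 0.0, X, y, 0.0, 0.0)
        assert enet_objective(np.zeros(p), 0.0, X, y, 3.0, 4.0) == base

    def test_matches_term_by_term_summation_oracle(self, rng):
        n, p = 8, 3
        X = rng.normal(size=(n, p))
        y = rng.integers(0, 2, n)
        w = rng.normal(size=p)
        b = 0.7
        lam1, lam2 = 0.3, 1.1
        total = 0.0
        for i in range(n):
            eta = b + sum(w[j] * X[i, j] for j in range(p))
            prob = 1.0 / (1.0 + np.exp(-eta))
            total += -(y[i] * np.log(prob) + (1 - y[i]) * np.log(1 - prob))
        total += lam1 * sum(abs(v) for v in w)
        total += lam2 / 2 * sum(v * v for v in w)
        assert enet_objective(w, b, X, y, lam1, lam2) == \
            pytest.approx(total, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            enet_objective(np.zeros(2), 0.0, X, np.zeros(5), 0, 0)


class TestFitEnet:
    def test_all_zero_solution_at_lambda_max(self, rng):
        X, y = _logistic_data(rng)
        Xs = _standardized(X)
        lm = lambda_max(Xs, y)
        m = fit_enet(Xs, y, lm * 1.0001, 0.5)
        assert np.all(m.w == 0)
        # intercept sits at the base-rate logit
        assert m.b == pytest.approx(np.log(y.mean() / (1 - y.mean())),
                                    abs=1e-3)
        # just below lambda_max at least one voxel enters
        m2 = fit_enet(Xs, y, lm * 0.95, 0.5)
        assert m2.active_set.size >= 1

    def test_ridge_only_matches_smooth_optimizer(self, rng):
        X, y = _logistic_data(rng, n=60, p=8)
        Xs = _standardized(X)
        lam2 = 2.0
        res = minimize(
            lambda prm: enet_objective(prm[:-1], prm[-1], Xs, y, 0.0, lam2),
            np.zeros(9), method="L-BFGS-B")
        m = fit_enet(Xs, y, 0.0, lam2)
        assert m.objective == pytest.approx(res.fun, abs=1e-6)

    def test_duplicated_column_gets_equal_weights(self, rng):
        X, y = _logistic_data(rng, n=80, p=5)
        X2 = np.column_stack([X, X[:, 0]])
        m = fit_enet(X2, y, 1.0, 2.0, kkt_tol=1e-8)
        assert m.w[0] == pytest.approx(m.w[5], abs=1e-6)
        assert m.w[0] != 0

    def test_kkt_conditions_hold_at_solution(self, rng):
        X, y = _logistic_data(rng)
        Xs = _standardized(X)
        lm = lambda_max(Xs, y)
        lam1, lam2 = 0.2 * lm, 0.05 * lm
        m = fit_enet(Xs, y, lam1, lam2)
        mu = expit(Xs @ m.w + m.b)
        g = Xs.T @ (mu - y)
        tol = 1e-3 * lm
        nz = m.active_set
        assert np.all(np.abs(g[nz] + lam2 * m.w[nz]
                             + lam1 * np.sign(m.w[nz])) <= tol)
        assert np.all(np.abs(g[m.w == 0]) <= lam1 + tol)
        assert abs((mu - y).sum()) <= tol

    def test_objective_history_is_monotone_nonincreasing(self, rng):
        X, y = _logistic_data(rng)
        m = fit_enet(X, y, 0.5, 0.5)
        assert m.history.size >= 2
        assert np.all(np.diff(m.history) <= 1e-9)

    def test_invariant_to_trial_order(self, rng):
        X, y = _logistic_data(rng, n=60, p=10)
        perm = rng.permutation(60)
        m1 = fit_enet(X, y, 1.0, 1.0, kkt_tol=1e-8)
        m2 = fit_enet(X[perm], y[perm], 1.0, 1.0, kkt_tol=1e-8)
        np.testing.assert_allclose(m1.w, m2.w, atol=1e-6)
        assert m1.b == pytest.approx(m2.b, abs=1e-6)

    def test_single_class_labels_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            fit_enet(X, np.ones(10, dtype=int), 1.0, 1.0)

    def test_negative_penalties_rejected(self, rng):
        X, y = _logistic_data(rng, n=20, p=3)
        with pytest.raises(ValueError):
            fit_enet(X, y, -1.0, 0.0)

    def test_cap_marks_model_capped(self, rng):
        X, y = _logistic_data(rng, n=60, p=20, k=10)
        m = fit_enet(_standardized(X), y, 0.05, 0.1, max_voxels=2)
        assert m.capped and not m.converged

    def test_nonconvergence_carries_diagnostics(self, rng):
        X, y = _logistic_data(rng, n=40, p=5)
        with pytest.raises(ConvergenceError) as exc:
            fit_enet(_standardized(X), y, 0.5, 5.0, max_iter=1)
        assert exc.value.n_iter >= 1
        assert np.isfinite(exc.value.objective)


class TestRegGrid:
    def test_default_grid_shape_and_ordering(self, rng):
        grid = RegGrid.from_lambda_max(10.0, n_lambda1=100, n_lambda2=11)
        assert grid.n_points == 1100
        assert np.all(np.diff(grid.lambda1_paths, axis=1) < 0)
        assert grid.lambda1_paths[0, 0] == pytest.approx(10.0)
        assert grid.lambda1_paths[0, -1] == pytest.approx(1.0)

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RegGrid(lambda2_values=np.array([1.0, 1.0]),
                    lambda1_paths=np.array([[3.0, 2.0], [3.0, 2.0]]))

    def test_nondecreasing_path_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            RegGrid(lambda2_values=np.array([1.0]),
                    lambda1_paths=np.array([[2.0, 2.0]]))

    def test_point_indexing_is_path_major(self):
        grid = RegGrid.from_lambda_max(8.0, n_lambda1=3, n_lambda2=2)
        lam1, lam2 = grid.point(4)
        assert lam2 == pytest.approx(grid.lambda2_values[1])
        assert lam1 == pytest.approx(grid.lambda1_paths[1, 1])


class TestGridFamily:
    def test_single_point_single_resample_reduces_to_fit_enet(self, rng):
        X, y = _logistic_data(rng, n=50, p=10)
        grid = RegGrid(lambda2_values=np.array([1.0]),
                       lambda1_paths=np.array([[2.0]]))
        plan = rm.make_cv_plan(50, 5, 1, seed=0, y=y)
        fam = fit_grid_family(X, y, grid, plan, max_voxels=None,
                              standardize=False, dtype=np.float64)
        rep, fold, train, test = next(plan.iter_splits())
        direct = fit_enet(X[train], y[train], 2.0, 1.0)
        idx, val, b = fam.weights[0][0]
        w = np.zeros(10)
        w[idx] = val
        np.testing.assert_allclose(w, direct.w, atol=1e-6)
        np.testing.assert_allclose(
            fam.scores[0][0], X[test] @ direct.w + direct.b, atol=1e-5)

    def test_warm_started_path_matches_cold_fits(self, tiny_dataset):
        ds, _ = tiny_dataset
        grid = rm.default_grid(ds.X, ds.y, n_lambda1=6, n_lambda2=3)
        plan = rm.make_cv_plan(ds.n_trials, 4, 1, seed=0, y=ds.y)
        fam = fit_grid_family(ds.X, ds.y, grid, plan, max_voxels=None,
                              dtype=np.float64)
        rep, fold, train, test = next(plan.iter_splits())
        Xtr = _standardized(ds.X[train])
        for g in range(grid.n_points):
            lam1, lam2 = grid.point(g)
            cold = fit_enet(Xtr, ds.y[train], lam1, lam2)
            idx, val, b = fam.weights[g][0]
            w = np.zeros(ds.n_voxels)
            w[idx] = val
            warm_obj = enet_objective(w, b, Xtr, ds.y[train], lam1, lam2)
            assert warm_obj == pytest.approx(cold.objective, rel=1e-6,
                                             abs=1e-6)

    def test_null_data_near_lambda_max_selects_nothing(self):
        spec = rm.SyntheticSpec(n_trials=120, n_voxels=200,
                                grid_shape=(10, 5, 4), n_signal_voxels=0,
                                n_signal_clusters=1, effect_size=0.0, seed=5)
        ds, _ = rm.make_trial_dataset(spec)
        lm_grid = rm.default_grid(ds.X, ds.y, n_lambda1=2, n_lambda2=1,
                                  lambda1_ratio=0.9)
        plan = rm.make_cv_plan(ds.n_trials, 5, 2, seed=1, y=ds.y)
        fam = fit_grid_family(ds.X, ds.y, lm_grid, plan)
        sizes = [len(idx) for idx, _, _ in fam.weights[0]]
        assert np.median(sizes) <= 1

    def test_active_set_grows_down_the_path_on_average(self, medium_run):
        fam = medium_run["family"]
        grid = medium_run["grid"]
        for path in range(grid.n_paths):
            sizes = []
            for i in range(grid.n_lambda1):
                g = path * grid.n_lambda1 + i
                if fam.capped[g]:
                    break
                sizes.append(np.mean([len(t[0]) for t in fam.weights[g]]))
            # non-increasing in lambda1 == non-decreasing down the path,
            # asserted in aggregate (strict per-point monotonicity is not
            # guaranteed)
            diffs = np.diff(sizes)
            assert diffs.mean() >= 0

    def test_capped_path_points_are_flagged_and_skipped(self, tiny_dataset):
        ds, _ = tiny_dataset
        grid = rm.default_grid(ds.X, ds.y, n_lambda1=5, n_lambda2=1,
                               lambda1_ratio=0.05)
        plan = rm.make_cv_plan(ds.n_trials, 4, 1, seed=0, y=ds.y)
        fam = fit_grid_family(ds.X, ds.y, grid, plan, max_voxels=3)
        assert fam.capped.any()
        first = int(np.flatnonzero(fam.capped)[0])
        # everything below the first capped point on the path is capped too
        assert fam.capped[first:].all()
        assert all(w is None for w in fam.weights[first])
        with pytest.raises(ValueError, match="capped"):
            fam.maps(first)

    def test_single_class_training_subset_rejected(self, rng):
        X = rng.normal(size=(12, 4))
        y = np.array([1, 0] + [0] * 10)
        grid = RegGrid(lambda2_values=np.array([1.0]),
                       lambda1_paths=np.array([[1.0]]))
        plan = rm.make_cv_plan(12, 2, 1, seed=3, stratified=False)
        with pytest.raises(ValueError, match="single class|fit failed"):
            fit_grid_family(X, y, grid, plan)
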