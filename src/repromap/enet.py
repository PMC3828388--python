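"""Elastic-net-penalized logistic regression over a regularization grid.

The decoder is a logistic regression on the voxel space whose weights w are
penalized by a combination of the l1 norm (sparsity / voxel selection) and
the squared l2 norm (shrinkage / grouping):

    J(w, b) = NLL(w, b; X, y) + lambda1 * ||w||_1 + (lambda2 / 2) * ||w||_2^2

with an unpenalized intercept b. The solver is a proximal-Newton scheme:
cyclic coordinate descent on the penalized IRLS quadratic approximation,
restricted to an active set, alternating with full KKT sweeps that screen in
violating coordinates; a step-halving safeguard keeps the objective monotone
across iterations.

Families of decoders are trained over a two-parameter grid — for each
lambda2, a descending lambda1 path warm-started from the previous solution
and screened with the sequential strong rule — across the B training subsets
of a resampling plan. This is a functionally equivalent, sequential
re-implementation of simultaneous GLM family training: the estimator is
identical, only the scheduling differs. A fit whose active set exceeds the
voxel cap is marked capped and its lambda1 path is not continued.

Implementation note: the numerical kernels work on the transposed
(features x samples) matrix so that per-feature sweeps stream contiguous
memory; they are JIT-compiled with numba.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .resampling import ResamplePlan

__all__ = [
    "EnetModel",
    "RegGrid",
    "ClassifierFamily",
    "ConvergenceError",
    "enet_objective",
    "lambda_max",
    "fit_enet",
    "fit_grid_family",
    "default_grid",
    "DesignCache",
    "make_design_cache",
]


class ConvergenceError(RuntimeError):
    """Solver failed to converge; carries iterate diagnostics."""

    def __init__(self, msg: str, *, n_iter: int, objective: float,
                 kkt_violation: float):
        super().__init__(
            f"{msg} (n_iter={n_iter}, objective={objective:.6g}, "
            f"kkt_violation={kkt_violation:.3g})"
        )
        self.n_iter = n_iter
        self.objective = objective
        self.kkt_violation = kkt_violation


@dataclass
class EnetModel:
    """A fitted elastic-net logistic decoder at one grid point."""

    w: np.ndarray
    b: float
    lambda1: float
    lambda2: float
    capped: bool = False
    converged: bool = True
    n_iter: int = 0
    objective: float = np.nan
    history: np.ndarray = field(default_factory=lambda: np.empty(0))
    grad: np.ndarray | None = field(default=None, repr=False)

    @property
    def active_set(self) -> np.ndarray:
        return np.flatnonzero(self.w)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b


def _nll(eta: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def enet_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray,
                   lambda1: float, lambda2: float) -> float:
    """Penalized negative log-likelihood J(w, b)."""
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or w.shape != (X.shape[1],) or y.shape != (X.shape[0],):
        raise ValueError("dimension mismatch between w, X and y")
    eta = X @ w + b
    return (_nll(eta, y) + lambda1 * np.abs(w).sum()
            + 0.5 * lambda2 * float(w @ w))


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda1 for which the all-zero weight map is optimal.

    At w = 0 with the intercept at its MLE (logit of the base rate), the
    subgradient condition gives lambda_max = max_i |x_i . (ybar - y)|.
    """
    y = np.asarray(y, dtype=np.float64)
    return float(np.abs((X.T @ (y.mean() - y)).astype(np.float64)).max())


@njit(cache=True, fastmath=True)
def _solve_restricted(Xat, yf, wa, b, mu, lam1, lam2, kkt_tol, tol, slack,
                      hist, cap, max_outer, max_pass):  # pragma: no cover
    """Proximal-Newton solve restricted to the active features.

    ``Xat`` is (k, n): one contiguous row per active feature. Outer loop:
    IRLS quadratic approximation; inner loop: cyclic coordinate descent with
    an unpenalized intercept; step halving keeps the objective monotone.
    Terminates when the restricted KKT residual falls below 0.5 * kkt_tol
    (status 0), the outer budget is exhausted (status 1), the nonzero count
    exceeds ``cap`` (status 2), or the objective change drops below ``tol``
    (status 3). ``wa``, ``mu`` and ``hist`` are updated in place; returns
    (b, status, cd_passes, hist_length).
    """
    k, n = Xat.shape
    eta = np.empty(n)
    sw = np.empty(n)
    r = np.empty(n)
    cn = np.empty(k)
    wa_old = np.empty(k)
    n_hist = 0
    passes = 0
    status = 1
    for _outer in range(max_outer):
        for i in range(n):
            eta[i] = b
        for j in range(k):
            wj = wa[j]
            if wj != 0.0:
                for i in range(n):
                    eta[i] += Xat[j, i] * wj
        obj = 0.0
        for i in range(n):
            e = eta[i]
            if e > 30.0:
                e = 30.0
            elif e < -30.0:
                e = -30.0
            eta[i] = e
            if e > 0.0:
                obj += e + np.log1p(np.exp(-e)) - yf[i] * e
            else:
                obj += np.log1p(np.exp(e)) - yf[i] * e
            mu[i] = 1.0 / (1.0 + np.exp(-e))
        for j in range(k):
            obj += lam1 * abs(wa[j]) + 0.5 * lam2 * wa[j] * wa[j]
        if n_hist == 0:
            hist[0] = obj
            n_hist = 1
        # restricted KKT residual
        s = 0.0
        for i in range(n):
            s += mu[i] - yf[i]
        rk = abs(s)
        for j in range(k):
            gj = 0.0
            for i in range(n):
                gj += Xat[j, i] * (mu[i] - yf[i])
            if wa[j] != 0.0:
                sgn = 1.0 if wa[j] > 0.0 else -1.0
                v = abs(gj + lam2 * wa[j] + lam1 * sgn)
            else:
                v = abs(gj) - lam1
                if v < 0.0:
                    v = 0.0
            if v > rk:
                rk = v
        if rk <= 0.5 * kkt_tol:
            status = 0
            break
        # IRLS quadratic weights and working residual
        for i in range(n):
            swi = mu[i] * (1.0 - mu[i])
            if swi < 1e-5:
                swi = 1e-5
            sw[i] = swi
            r[i] = (yf[i] - mu[i]) / swi
        wmax = 0.0
        for j in range(k):
            c = 0.0
            for i in range(n):
                c += sw[i] * Xat[j, i] * Xat[j, i]
            cn[j] = c
            wa_old[j] = wa[j]
            if abs(wa[j]) > wmax:
                wmax = abs(wa[j])
        cmax = 0.0
        for j in range(k):
            if cn[j] > cmax:
                cmax = cn[j]
        b_old = b
        # coefficient tolerance tight enough to support the KKT target
        cd_tol = 1e-6 * (1.0 + wmax)
        alt = kkt_tol / (10.0 * (1.0 + cmax))
        if alt < cd_tol:
            cd_tol = alt
        # cyclic coordinate descent on the quadratic subproblem
        for _p in range(max_pass):
            passes += 1
            maxd = 0.0
            for j in range(k):
                c = cn[j]
                if c <= 0.0:
                    continue
                rho = c * wa[j]
                for i in range(n):
                    rho += sw[i] * Xat[j, i] * r[i]
                if rho > lam1:
                    wnew = (rho - lam1) / (c + lam2)
                elif rho < -lam1:
                    wnew = (rho + lam1) / (c + lam2)
                else:
                    wnew = 0.0
                d = wnew - wa[j]
                if d != 0.0:
                    for i in range(n):
                        r[i] -= Xat[j, i] * d
                    wa[j] = wnew
                    if abs(d) > maxd:
                        maxd = abs(d)
            num = 0.0
            den = 0.0
            for i in range(n):
                num += sw[i] * r[i]
                den += sw[i]
            db = num / den
            if db != 0.0:
                b += db
                for i in range(n):
                    r[i] -= db
                if abs(db) > maxd:
                    maxd = abs(db)
            if maxd < cd_tol:
                break
        # objective at the proposed point, with step halving
        bound = hist[n_hist - 1] + slack * (1.0 + abs(hist[n_hist - 1]))
        obj_new = np.inf
        for _h in range(31):
            obj_new = 0.0
            for i in range(n):
                eta[i] = b
            for j in range(k):
                wj = wa[j]
                if wj != 0.0:
                    for i in range(n):
                        eta[i] += Xat[j, i] * wj
            for i in range(n):
                e = eta[i]
                if e > 30.0:
                    e = 30.0
                elif e < -30.0:
                    e = -30.0
                if e > 0.0:
                    obj_new += e + np.log1p(np.exp(-e)) - yf[i] * e
                else:
                    obj_new += np.log1p(np.exp(e)) - yf[i] * e
            for j in range(k):
                obj_new += lam1 * abs(wa[j]) + 0.5 * lam2 * wa[j] * wa[j]
            if obj_new <= bound:
                break
            for j in range(k):
                wa[j] = 0.5 * (wa[j] + wa_old[j])
            b = 0.5 * (b + b_old)
        if obj_new > bound:
            for j in range(k):
                wa[j] = wa_old[j]
            b = b_old
            obj_new = hist[n_hist - 1]
        if obj_new < hist[n_hist - 1]:
            hist[n_hist] = obj_new
        else:
            hist[n_hist] = hist[n_hist - 1]
        n_hist += 1
        if cap > 0:
            nnz = 0
            for j in range(k):
                if wa[j] != 0.0:
                    nnz += 1
            if nnz > cap:
                status = 2
                break
        if abs(hist[n_hist - 1] - hist[n_hist - 2]) <= \
                tol * (1.0 + abs(hist[n_hist - 1])):
            status = 3
            break
    return b, status, passes, n_hist


@njit(cache=True, fastmath=True)
def _fit_path(Xt, yf, lam1_path, lam2, kkt_tol, tol, slack, cap,
              b0):  # pragma: no cover
    """Warm-started descending lambda1 path on one training subset.

    ``Xt`` is the transposed (p, n) feature matrix, C-contiguous. Returns
    (W, bs, fitted, capped_from, err_point): dense weight rows per path
    point, intercepts, a fitted flag per point, the index at which the
    voxel cap truncated the path (== len(path) if never), and the path
    index of a convergence failure (-1 if none).
    """
    p, n = Xt.shape
    n_pts = lam1_path.size
    W = np.zeros((n_pts, p))
    bs = np.zeros(n_pts)
    fitted = np.zeros(n_pts, dtype=np.bool_)
    capped_from = n_pts
    err_point = -1

    w = np.zeros(p)
    b = b0
    mu = np.empty(n)
    g = np.empty(p)
    resid = np.empty(n)
    have_grad = False
    active_mask = np.zeros(p, dtype=np.bool_)
    hist = np.empty(102)
    lam1_prev = -1.0

    for ipt in range(n_pts):
        lam1 = lam1_path[ipt]
        if have_grad and lam1_prev > 0.0:
            strong = 2.0 * lam1 - lam1_prev
            for j in range(p):
                if abs(g[j]) > strong:
                    active_mask[j] = True
        done = False
        capped_here = False
        for _round in range(50):
            act = np.flatnonzero(active_mask)
            k = act.size
            Xat = np.empty((k, n), dtype=Xt.dtype)
            wa = np.empty(k)
            for jj in range(k):
                row = act[jj]
                wa[jj] = w[row]
                for i in range(n):
                    Xat[jj, i] = Xt[row, i]
            tol_eff = min(tol, 1e-6 * kkt_tol)
            b, status, _passes, _n_hist = _solve_restricted(
                Xat, yf, wa, b, mu, lam1, lam2, kkt_tol, tol_eff, slack,
                hist, cap, 100, 10)
            for j in range(p):
                w[j] = 0.0
            for jj in range(k):
                w[act[jj]] = wa[jj]
            if status == 2:
                capped_here = True
                break
            if status == 1:
                # outer budget exhausted: recompute mu at the final iterate
                for i in range(n):
                    e = b
                    for jj in range(k):
                        if wa[jj] != 0.0:
                            e += Xat[jj, i] * wa[jj]
                    if e > 30.0:
                        e = 30.0
                    elif e < -30.0:
                        e = -30.0
                    mu[i] = 1.0 / (1.0 + np.exp(-e))
            # full KKT sweep
            for i in range(n):
                resid[i] = mu[i] - yf[i]
            s = 0.0
            for i in range(n):
                s += resid[i]
            kkt_viol = abs(s)
            n_new = 0
            for j in range(p):
                gj = 0.0
                for i in range(n):
                    gj += Xt[j, i] * resid[i]
                g[j] = gj
                if w[j] != 0.0:
                    sgn = 1.0 if w[j] > 0.0 else -1.0
                    v = abs(gj + lam2 * w[j] + lam1 * sgn)
                else:
                    v = abs(gj) - lam1
                    if v < 0.0:
                        v = 0.0
                if v > kkt_viol:
                    kkt_viol = v
                if v > 0.5 * kkt_tol and not active_mask[j]:
                    active_mask[j] = True
                    n_new += 1
            have_grad = True
            if kkt_viol <= kkt_tol:
                done = True
                break
            if n_new == 0:
                if status == 3 and kkt_viol <= 100.0 * kkt_tol:
                    done = True
                    break
                err_point = ipt
                return W, bs, fitted, capped_from, err_point
        if capped_here:
            capped_from = ipt
            break
        if not done:
            err_point = ipt
            return W, bs, fitted, capped_from, err_point
        for j in range(p):
            W[ipt, j] = w[j]
        bs[ipt] = b
        fitted[ipt] = True
        lam1_prev = lam1
        # keep only the current support in the active mask
        for j in range(p):
            active_mask[j] = w[j] != 0.0
    return W, bs, fitted, capped_from, err_point


def fit_enet(X: np.ndarray, y: np.ndarray, lambda1: float, lambda2: float,
             warm_start: EnetModel | None = None,
             max_voxels: int | None = None,
             tol: float = 1e-7, max_iter: int = 10_000,
             kkt_tol: float | None = None,
             init_active: np.ndarray | None = None,
             keep_grad: bool = False) -> EnetModel:
    """Fit one elastic-net logistic decoder.

    The returned solution satisfies the KKT conditions of the penalized
    objective to ``kkt_tol`` (default: 1e-4 relative to the data's gradient
    scale); ``tol`` is the relative objective-change tolerance and
    ``max_iter`` a budget on total coordinate-descent passes.
    ``init_active`` seeds the active set (e.g. strong-rule candidates along
    a path). If the number of nonzero weights exceeds ``max_voxels`` the
    fit returns immediately with ``capped=True`` (no statistics should be
    read from it). The objective history across iterations is recorded on
    the returned model and is non-increasing.
    """
    X = np.asarray(X)
    if X.dtype not in (np.float32, np.float64):
        X = X.astype(np.float64)
    y01 = np.asarray(y)
    if np.unique(y01).size < 2:
        raise ValueError("y contains a single class; cannot fit a classifier")
    yf = y01.astype(np.float64)
    n, p = X.shape
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalty weights must be non-negative")

    if warm_start is not None:
        w = warm_start.w.astype(np.float64).copy()
        b = float(warm_start.b)
    else:
        w = np.zeros(p)
        pbar = min(max(yf.mean(), 1e-6), 1 - 1e-6)
        b = float(np.log(pbar / (1 - pbar)))
    if kkt_tol is None:
        kkt_tol = 1e-4 * max(1.0, lambda_max(X, yf))
    # numerical slack for objective comparisons, scaled to the dtype
    slack = 100.0 * float(np.finfo(X.dtype).eps)

    active_mask = np.zeros(p, dtype=bool)
    active_mask[w != 0] = True
    if init_active is not None:
        active_mask[np.asarray(init_active)] = True

    history: list[float] = []
    total_passes = 0
    converged = False
    kkt_viol = np.inf
    g = None
    mu = np.empty(n)
    cap = -1 if max_voxels is None else int(max_voxels)
    hist_buf = np.empty(102)

    for _round in range(50):
        act = np.flatnonzero(active_mask)
        Xat = np.ascontiguousarray(X[:, act].T)
        wa = w[act].astype(np.float64)
        tol_eff = min(float(tol), 1e-6 * float(kkt_tol))
        b, status, passes, n_hist = _solve_restricted(
            Xat, yf, wa, b, mu, float(lambda1), float(lambda2),
            float(kkt_tol), tol_eff, slack, hist_buf, cap, 100, 10)
        b = float(b)
        total_passes += int(passes)
        seg = hist_buf[:n_hist]
        if history:  # stitch across rounds, keeping global monotonicity
            seg = np.minimum.accumulate(
                np.concatenate([[history[-1]], seg]))[1:]
        history.extend(float(v) for v in seg)
        w.fill(0.0)
        w[act] = wa
        if status == 2:
            return EnetModel(w=w, b=b, lambda1=lambda1, lambda2=lambda2,
                             capped=True, converged=False,
                             n_iter=total_passes, objective=history[-1],
                             history=np.asarray(history))
        if total_passes > max_iter:
            raise ConvergenceError(
                "coordinate-descent pass budget exhausted",
                n_iter=total_passes, objective=history[-1],
                kkt_violation=kkt_viol)
        if status == 1:
            eta = (X[:, act] @ wa).astype(np.float64) + b
            np.clip(eta, -30.0, 30.0, out=eta)
            mu = 1.0 / (1.0 + np.exp(-eta))
        # full KKT sweep over all features
        g = (X.T @ (mu - yf)).astype(np.float64)
        viol = np.maximum(np.abs(g) - lambda1, 0.0)
        nz = np.flatnonzero(w)
        if nz.size:
            viol[nz] = np.abs(g[nz] + lambda2 * w[nz]
                              + lambda1 * np.sign(w[nz]))
        kkt_viol = max(float(viol.max(initial=0.0)),
                       abs(float(np.sum(mu - yf))))
        if kkt_viol <= kkt_tol:
            converged = True
            break
        newly = (viol > 0.5 * kkt_tol) & ~active_mask
        if not newly.any():
            if status == 3 and kkt_viol <= 100 * kkt_tol:
                # objective converged to ``tol``; the residual KKT slack is
                # below the statistically meaningful scale
                converged = True
                break
            raise ConvergenceError(
                "restricted solve cannot reach the KKT tolerance",
                n_iter=total_passes, objective=history[-1],
                kkt_violation=kkt_viol)
        active_mask |= newly
    if not converged:
        raise ConvergenceError(
            "active-set rounds exhausted without convergence",
            n_iter=total_passes, objective=history[-1],
            kkt_violation=kkt_viol)
    return EnetModel(w=w, b=b, lambda1=lambda1, lambda2=lambda2,
                     converged=True, n_iter=total_passes,
                     objective=history[-1], history=np.asarray(history),
                     grad=g if keep_grad else None)


@dataclass(frozen=True)
class RegGrid:
    """Ordered (lambda1, lambda2) grid, structured as descending lambda1
    paths, one path per lambda2 value."""

    lambda2_values: np.ndarray       # (n_paths,)
    lambda1_paths: np.ndarray        # (n_paths, n_lambda1), rows descending

    def __post_init__(self):
        paths = np.asarray(self.lambda1_paths, dtype=float)
        if paths.ndim != 2:
            raise ValueError("lambda1_paths must be 2-D")
        if np.any(np.diff(paths, axis=1) >= 0):
            raise ValueError("lambda1 paths must be strictly decreasing")
        pairs = {(float(l1), float(l2))
                 for l2, row in zip(self.lambda2_values, paths)
                 for l1 in row}
        if len(pairs) != paths.size:
            raise ValueError("duplicate (lambda1, lambda2) pairs in grid")

    @property
    def n_paths(self) -> int:
        return self.lambda1_paths.shape[0]

    @property
    def n_lambda1(self) -> int:
        return self.lambda1_paths.shape[1]

    @property
    def n_points(self) -> int:
        return self.lambda1_paths.size

    def point(self, g: int) -> tuple[float, float]:
        """(lambda1, lambda2) of grid point ``g`` (path-major order)."""
        path, i = divmod(g, self.n_lambda1)
        return float(self.lambda1_paths[path, i]), \
            float(self.lambda2_values[path])

    @property
    def lambda1(self) -> np.ndarray:
        return self.lambda1_paths.ravel()

    @property
    def lambda2(self) -> np.ndarray:
        return np.repeat(np.asarray(self.lambda2_values, float),
                         self.n_lambda1)

    @classmethod
    def from_lambda_max(cls, lam_max: float, n_lambda1: int = 100,
                        n_lambda2: int = 11, lambda1_ratio: float = 0.1,
                        lambda2_ratios: tuple[float, float] = (1e-3, 1.0),
                        ) -> "RegGrid":
        """Default grid: ``n_lambda2`` log-spaced l2 weights times an
        ``n_lambda1``-point log-spaced descending l1 path from lambda_max
        down to ``lambda1_ratio * lambda_max`` (11 x 100 = 1,100 points by
        default)."""
        l1 = np.geomspace(lam_max, lambda1_ratio * lam_max, n_lambda1)
        l2 = lam_max * np.geomspace(lambda2_ratios[0], lambda2_ratios[1],
                                    n_lambda2)
        return cls(lambda2_values=l2,
                   lambda1_paths=np.tile(l1, (n_lambda2, 1)))


def default_grid(X: np.ndarray, y: np.ndarray, standardize: bool = True,
                 **kwargs) -> RegGrid:
    """Build the default grid from the data's lambda_max."""
    X = np.asarray(X, dtype=float)
    if standardize:
        sd = X.std(axis=0)
        sd[sd < 1e-12] = 1.0
        X = (X - X.mean(axis=0)) / sd
    return RegGrid.from_lambda_max(lambda_max(X, np.asarray(y, float)),
                                   **kwargs)


@dataclass
class ClassifierFamily:
    """B sparse weight maps plus held-out decision scores per grid point.

    ``weights[g][b]`` is ``(indices, values, intercept)`` or ``None`` when
    the fit was skipped because the path hit the voxel cap; ``scores[g][b]``
    are the decision scores of resample ``b``'s held-out trials.
    """

    grid: RegGrid
    plan: ResamplePlan
    y: np.ndarray
    n_voxels: int
    weights: list
    scores: list
    test_indices: list
    repeat_of: np.ndarray
    capped: np.ndarray
    max_voxels: int | None = None

    @property
    def B(self) -> int:
        return len(self.test_indices)

    def maps(self, g: int) -> list:
        """Sparse weight maps (indices, values) for grid point ``g``."""
        if self.capped[g]:
            raise ValueError(f"grid point {g} is capped; no maps available")
        return [(idx, val) for idx, val, _b in self.weights[g]]

    def selection_profile(self, g: int):
        from .metrics import selection_profile
        return selection_profile(self.maps(g), n_voxels=self.n_voxels)


@dataclass
class DesignCache:
    """Per-resample standardized training/test matrices, reusable across
    label permutations (standardization depends only on the split)."""

    entries: list  # (Xt (p, n_train) dtype, Xte (n_test, p) f64, test, rep)
    n_voxels: int


def make_design_cache(X: np.ndarray, plan: ResamplePlan,
                      standardize: bool = True,
                      dtype=np.float32) -> DesignCache:
    """Precompute the per-split standardized matrices for a plan."""
    X = np.asarray(X, dtype=np.float64)
    entries = []
    for _b, (rep, train, test) in enumerate(_iter_train_test(plan)):
        Xtr = X[train]
        if standardize:
            mean = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd[sd < 1e-12] = 1.0
            Xtr = (Xtr - mean) / sd
            Xte = (X[test] - mean) / sd
        else:
            Xte = X[test].copy()
        entries.append((np.ascontiguousarray(Xtr.T, dtype=dtype),
                        np.asarray(Xte, dtype=np.float64),
                        np.asarray(train), np.asarray(test), rep))
    return DesignCache(entries=entries, n_voxels=X.shape[1])


def _iter_train_test(plan: ResamplePlan):
    if plan.kind == "cv":
        for rep, _fold, train, test in plan.iter_splits():
            yield rep, train, test
    elif plan.kind == "bootstrap":
        for b in range(plan.n_splits):
            yield b, plan.indices[b], plan.oob[b]
    else:
        raise ValueError(f"cannot train on a plan of kind {plan.kind!r}")


def fit_grid_family(X: np.ndarray, y: np.ndarray, grid: RegGrid,
                    plan: ResamplePlan, max_voxels: int | None = 1000,
                    standardize: bool = True, tol: float = 1e-7,
                    dtype=np.float32,
                    cache: DesignCache | None = None) -> ClassifierFamily:
    """Train the full grid of decoders on every resample of ``plan``.

    Features are z-scored on each training split (the same transform is
    applied to that split's held-out trials) unless ``standardize=False``.
    Models along each lambda1 path are warm-started from the previous
    solution and screened with the sequential strong rule; once a path hits
    the voxel cap on some resample, the capped point and the remainder of
    that path are skipped for that resample and the affected grid points
    are flagged capped. ``dtype`` controls the working precision of the
    feature matrix (single precision by default: the gradient sweeps are
    memory-bandwidth-bound and the KKT tolerance is far above
    single-precision rounding; pass ``np.float64`` for strict
    double-precision training). A precomputed ``cache`` (see
    :func:`make_design_cache`) lets permutation reruns skip the
    standardization work, which does not depend on the labels.
    """
    y = np.asarray(y)
    if cache is None:
        cache = make_design_cache(X, plan, standardize=standardize,
                                  dtype=dtype)
    p = cache.n_voxels
    n_pts = grid.n_points
    weights = [[] for _ in range(n_pts)]
    scores = [[] for _ in range(n_pts)]
    test_indices: list[np.ndarray] = []
    repeat_of: list[int] = []
    capped = np.zeros(n_pts, dtype=bool)
    slack = 100.0 * float(np.finfo(cache.entries[0][0].dtype).eps)
    cap = -1 if max_voxels is None else int(max_voxels)

    for b, (Xt, Xte, train, test, rep) in enumerate(cache.entries):
        ytr = y[train]
        if np.unique(ytr).size < 2:
            raise ValueError(f"training subset {b} has a single class")
        yf = ytr.astype(np.float64)
        kkt_tol = 1e-4 * max(
            1.0, float(np.abs((Xt @ (yf.mean() - yf))
                              .astype(np.float64)).max()))
        pbar = min(max(yf.mean(), 1e-6), 1 - 1e-6)
        b0 = float(np.log(pbar / (1 - pbar)))
        test_indices.append(test)
        repeat_of.append(rep)
        for path in range(grid.n_paths):
            lam2 = float(grid.lambda2_values[path])
            lam1s = np.ascontiguousarray(grid.lambda1_paths[path],
                                         dtype=np.float64)
            W, bs, fitted, capped_from, err_point = _fit_path(
                Xt, yf, lam1s, lam2, float(kkt_tol), float(tol), slack,
                cap, b0)
            if err_point >= 0:
                g = path * grid.n_lambda1 + int(err_point)
                raise RuntimeError(
                    f"fit failed to converge at grid point {g} "
                    f"(lambda1={lam1s[err_point]:.4g}, lambda2={lam2:.4g}),"
                    f" resample {b}")
            S = Xte @ W.T + bs  # held-out decision scores, all path points
            for i in range(grid.n_lambda1):
                g = path * grid.n_lambda1 + i
                if i >= capped_from:
                    capped[g] = True
                    weights[g].append(None)
                    scores[g].append(None)
                    continue
                idx = np.flatnonzero(W[i]).astype(np.int32)
                weights[g].append((idx, W[i, idx].copy(), float(bs[i])))
                scores[g].append(S[:, i].astype(np.float64))
    return ClassifierFamily(grid=grid, plan=plan, y=y, n_voxels=p,
                            weights=weights, scores=scores,
                            test_indices=test_indices,
                            repeat_of=np.asarray(repeat_of),
                            capped=capped, max_voxels=max_voxels)
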