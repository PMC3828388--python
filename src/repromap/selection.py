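"""Multi-objective model selection over the regularization grid.

Each non-capped grid point is a candidate decoder summarised by the pair
(reproducibility psi_sp, accuracy Az). The candidate "best" decoders are the
Pareto-optimal ones — those not dominated by any other point on both axes.
Three concrete strategies are provided:

* ``MaxAz``     — maximise prediction accuracy (the conventional choice);
* ``MaxReprod`` — maximise reproducibility;
* ``JointSP``   — minimise Euclidean distance to the utopia point
  (psi_sp, Az) = (1, 1), balancing the two objectives.

A provable consequence of the JointSP definition (with ties broken toward
larger psi_sp) is the tradeoff ordering psi_sp(JointSP) >= psi_sp(MaxAz)
and Az(MaxAz) >= Az(JointSP): moving from MaxAz to JointSP can only trade
accuracy for reproducibility, never lose both.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .metrics import GridSummary

__all__ = ["SelectionResult", "pareto_front", "convex_hull", "choose",
           "select_models", "plot_tradeoff"]

STRATEGIES = ("MaxAz", "MaxReprod", "JointSP")


@dataclass
class SelectionResult:
    """Pareto front, hull boundary and the per-strategy chosen grid points."""

    pareto_indices: np.ndarray
    hull_indices: np.ndarray
    chosen: dict


def pareto_front(points: np.ndarray) -> np.ndarray:
    """Indices of non-dominated points among (psi_sp, Az) pairs.

    Point i is on the front iff no j has psi_j >= psi_i and Az_j >= Az_i
    with at least one inequality strict. Implemented as a sort-and-sweep;
    duplicates of a front point are all kept (mutual non-domination).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = pts.shape[0]
    if n == 0:
        return np.empty(0, dtype=np.int64)
    order = np.lexsort((-pts[:, 1], -pts[:, 0]))  # psi desc, then Az desc
    keep = np.zeros(n, dtype=bool)
    best_az_strictly_higher_psi = -np.inf
    i = 0
    while i < n:
        j = i
        while j < n and pts[order[j], 0] == pts[order[i], 0]:
            j += 1
        group = order[i:j]
        group_max_az = pts[group, 1].max()
        if group_max_az > best_az_strictly_higher_psi:
            keep[group[pts[group, 1] == group_max_az]] = True
        best_az_strictly_higher_psi = max(best_az_strictly_higher_psi,
                                          group_max_az)
        i = j
    return np.flatnonzero(keep)


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Vertex indices of the 2-D convex hull, counter-clockwise.

    Degenerate inputs are handled explicitly: fewer than 3 distinct points
    return all distinct points; collinear points return the two extreme
    endpoints.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    distinct = np.unique(pts, axis=0)
    if distinct.shape[0] < 3:
        out = []
        for d in distinct:
            out.append(int(np.flatnonzero((pts == d).all(axis=1))[0]))
        return np.asarray(sorted(out), dtype=np.int64)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # collinear: return the two extreme endpoints
        d = pts - pts.mean(axis=0)
        proj = d @ (d[np.abs(d).sum(axis=1).argmax()])
        return np.unique([int(proj.argmin()), int(proj.argmax())]).astype(np.int64)
    return hull.vertices.astype(np.int64)  # scipy returns CCW order in 2-D


def _joint_distance(psi: np.ndarray, az: np.ndarray,
                    weights: tuple[float, float] = (1.0, 1.0)) -> np.ndarray:
    return np.sqrt(weights[0] * (1.0 - psi) ** 2
                   + weights[1] * (1.0 - az) ** 2)


def choose(summary: GridSummary, strategy: str,
           joint_weights: tuple[float, float] = (1.0, 1.0)) -> int:
    """Pick a grid point by strategy; deterministic tie-breaking.

    Ties are broken toward larger psi_sp, then larger lambda1 (the sparser
    model), then the lowest grid index.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; one of {STRATEGIES}")
    eligible = np.flatnonzero(summary.eligible
                              & np.isfinite(summary.Az)
                              & np.isfinite(summary.psi_sp))
    if eligible.size == 0:
        raise ValueError("no eligible grid points to select from")
    psi = summary.psi_sp[eligible]
    az = summary.Az[eligible]
    lam1 = summary.lambda1[eligible]
    if strategy == "MaxAz":
        crit = az
    elif strategy == "MaxReprod":
        crit = psi
    else:
        crit = -_joint_distance(psi, az, joint_weights)
    best = crit.max()
    cand = np.flatnonzero(np.isclose(crit, best, rtol=0, atol=1e-12))
    # tie-breaks: larger psi_sp, larger lambda1, lowest index
    order = np.lexsort((eligible[cand], -lam1[cand], -psi[cand]))
    return int(eligible[cand[order[0]]])


def select_models(summary: GridSummary,
                  joint_weights: tuple[float, float] = (1.0, 1.0),
                  ) -> SelectionResult:
    """Pareto front, hull and all three strategy choices for a summary."""
    eligible = np.flatnonzero(summary.eligible
                              & np.isfinite(summary.Az)
                              & np.isfinite(summary.psi_sp))
    if eligible.size == 0:
        raise ValueError("no eligible grid points")
    pts = np.column_stack([summary.psi_sp[eligible], summary.Az[eligible]])
    front = eligible[pareto_front(pts)]
    hull = eligible[convex_hull(pts)]
    chosen = {s: choose(summary, s, joint_weights) for s in STRATEGIES}
    return SelectionResult(pareto_indices=np.sort(front),
                           hull_indices=hull, chosen=chosen)


def plot_tradeoff(summary: GridSummary, result: SelectionResult | None = None,
                  thresholds: dict | None = None, out_path=None):
    """Two-panel reproducibility-vs-accuracy scatter with hull and picks.

    Left: psi_sp vs Az; right: psi_|z| vs Az. Interior points in gray, hull
    boundary in black, the MaxAz and JointSP picks highlighted. Optional
    ``thresholds`` dict (keys 'Az', 'psi_sp', 'psi_z') draws permutation
    significance lines.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result is None:
        result = select_models(summary)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
    for ax, stat, name in ((axes[0], summary.psi_sp, "psi_sp"),
                           (axes[1], summary.psi_z, "psi_|z|")):
        ok = summary.eligible & np.isfinite(stat) & np.isfinite(summary.Az)
        ax.scatter(stat[ok], summary.Az[ok], s=8, c="0.7", label="grid")
        if name == "psi_sp" and result.hull_indices.size >= 2:
            hx = np.append(stat[result.hull_indices],
                           stat[result.hull_indices[0]])
            hy = np.append(summary.Az[result.hull_indices],
                           summary.Az[result.hull_indices[0]])
            ax.plot(hx, hy, "k-", lw=1, label="convex hull")
        for strat, color in (("MaxAz", "red"), ("JointSP", "magenta")):
            g = result.chosen[strat]
            ax.scatter([stat[g]], [summary.Az[g]], c=color, s=60,
                       zorder=5, label=strat)
        if thresholds:
            if "Az" in thresholds:
                ax.axhline(thresholds["Az"], ls=":", c="k", lw=0.8)
            key = "psi_sp" if name == "psi_sp" else "psi_z"
            if key in thresholds:
                ax.axvline(thresholds[key], ls=":", c="k", lw=0.8)
        ax.set_xlabel(name)
        ax.set_ylabel("Az")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
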