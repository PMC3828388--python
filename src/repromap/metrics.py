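"""Prediction accuracy (Az) and reproducibility statistics.

From the B weight maps of one grid point we compute, per voxel, the
selection probability v_i (fraction of maps in which the voxel carries a
nonzero weight), the mean weight mu_i and its standard error se_i over the B
resampled estimates (unselected entries counted as zero weight), and the
standard score z_i = mu_i / se_i. Two scalar reproducibility summaries
follow:

    psi_sp  = sum_i v_i^2   / sum_i v_i   (mean selection probability)
    psi_|z| = sum_i v_i|z_i| / sum_i v_i  (mean absolute z-score)

Both are selection-probability-weighted means, normalized by the mean number
of selected voxels n_bar = sum_i v_i. psi_sp is the expected selection
probability of a voxel with nonzero weight drawn at random from one of the
maps; it lies in (0, 1] and equals 1 exactly when every v_i is 0 or 1
(perfect support reproducibility). psi_|z| is the analogous expected z-score
magnitude and is unbounded above.

Prediction accuracy Az is the area under the ROC curve of the held-out
decision scores, computed per cross-validation repeat (pooling the repeat's
folds) and averaged across repeats.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .enet import ClassifierFamily

__all__ = [
    "SelectionProfile",
    "GridSummary",
    "auc",
    "selection_profile",
    "psi_sp",
    "psi_z",
    "summarize_grid",
]


@dataclass
class SelectionProfile:
    """Per-voxel selection probabilities, weight means/SEs and z-scores."""

    v: np.ndarray
    mu: np.ndarray
    se: np.ndarray
    z: np.ndarray
    B: int

    @property
    def n_bar(self) -> float:
        """Mean number of voxels selected per map."""
        return float(self.v.sum())


@dataclass
class GridSummary:
    """Per-grid-point accuracy and reproducibility summaries."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    Az: np.ndarray
    psi_sp: np.ndarray
    psi_z: np.ndarray
    n_bar: np.ndarray
    capped: np.ndarray
    empty: np.ndarray

    @property
    def n_points(self) -> int:
        return self.Az.size

    @property
    def eligible(self) -> np.ndarray:
        """Points usable for model selection: not capped, not all-empty."""
        return ~self.capped & ~self.empty

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda1": self.lambda1, "lambda2": self.lambda2,
            "Az": self.Az, "psi_sp": self.psi_sp, "psi_z": self.psi_z,
            "n_bar": self.n_bar, "capped": self.capped, "empty": self.empty,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GridSummary":
        return cls(lambda1=df["lambda1"].to_numpy(float),
                   lambda2=df["lambda2"].to_numpy(float),
                   Az=df["Az"].to_numpy(float),
                   psi_sp=df["psi_sp"].to_numpy(float),
                   psi_z=df["psi_z"].to_numpy(float),
                   n_bar=df["n_bar"].to_numpy(float),
                   capped=df["capped"].to_numpy(bool),
                   empty=df["empty"].to_numpy(bool))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney, ties counted half).

    Equals P(score_1 > score_0) + 0.5 * P(tie) for a random positive/negative
    pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute Az")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def selection_profile(maps, n_voxels: int | None = None) -> SelectionProfile:
    """Aggregate B weight maps into a per-voxel selection profile.

    ``maps`` may be dense p-vectors or sparse ``(indices, values)`` pairs.
    Means and standard errors are computed over all B maps with unselected
    entries counted as zero; the SE is the sample standard deviation (ddof=1)
    of the B resampled weight estimates. Where se = 0 but v > 0 (identical
    nonzero weight in every map) z is set to a signed infinity sentinel.
    """
    maps = list(maps)
    B = len(maps)
    if B < 1:
        raise ValueError("need at least one weight map")
    if isinstance(maps[0], tuple):
        if n_voxels is None:
            raise ValueError("n_voxels required for sparse maps")
        count = np.zeros(n_voxels)
        s1 = np.zeros(n_voxels)
        s2 = np.zeros(n_voxels)
        for idx, val in maps:
            np.add.at(count, idx, 1.0)
            np.add.at(s1, idx, val)
            np.add.at(s2, idx, np.asarray(val) ** 2)
    else:
        W = np.asarray(maps, dtype=float)
        n_voxels = W.shape[1]
        count = (W != 0).sum(axis=0).astype(float)
        s1 = W.sum(axis=0)
        s2 = (W ** 2).sum(axis=0)
    v = count / B
    mu = s1 / B
    if B > 1:
        var = np.maximum(s2 - B * mu ** 2, 0.0) / (B - 1)
        se = np.sqrt(var)
    else:
        se = np.zeros(n_voxels)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mu / np.where(se > 0, se, 1.0),
                     np.where(v > 0, np.sign(mu) * np.inf, 0.0))
    return SelectionProfile(v=v, mu=mu, se=se, z=z, B=B)


def psi_sp(profile: SelectionProfile) -> float:
    """Mean selection probability of the profile; in (0, 1]."""
    v = profile.v
    n_bar = v.sum()
    if n_bar <= 0:
        raise ValueError("psi_sp is undefined: no voxel was ever selected")
    return float((v ** 2).sum() / n_bar)


def psi_z(profile: SelectionProfile, on_infinite: str = "exclude") -> float:
    """Selection-probability-weighted mean absolute z-score; >= 0.

    Voxels with the infinite-z sentinel (se = 0, v > 0) are excluded with a
    warning by default; ``on_infinite='propagate'`` returns inf instead.
    """
    v = profile.v.copy()
    if v.sum() <= 0:
        raise ValueError("psi_z is undefined: no voxel was ever selected")
    absz = np.abs(profile.z)
    inf_mask = np.isinf(absz) & (v > 0)
    if inf_mask.any():
        if on_infinite == "propagate":
            return float("inf")
        warnings.warn(
            f"excluding {int(inf_mask.sum())} voxel(s) with zero weight "
            "standard error from psi_|z|", stacklevel=2)
        v = np.where(inf_mask, 0.0, v)
        if v.sum() <= 0:
            raise ValueError("psi_z undefined: all selected voxels had se=0")
    return float((v * np.where(v > 0, absz, 0.0)).sum() / v.sum())


def summarize_grid(family: ClassifierFamily,
                   az_aggregation: str = "pooled") -> GridSummary:
    """Compute Az, psi_sp, psi_|z| and n_bar at every grid point.

    Az pools each repeat's held-out scores into one ROC and averages across
    repeats (``az_aggregation='per_fold'`` instead averages per-fold AUCs).
    Capped grid points and points whose maps are all empty are flagged and
    carry NaN statistics.
    """
    grid = family.grid
    n_pts = grid.n_points
    Az = np.full(n_pts, np.nan)
    psp = np.full(n_pts, np.nan)
    pz = np.full(n_pts, np.nan)
    nbar = np.full(n_pts, np.nan)
    empty = np.zeros(n_pts, dtype=bool)
    y = np.asarray(family.y)
    groups = np.unique(family.repeat_of)
    for g in range(n_pts):
        if family.capped[g]:
            continue
        prof = family.selection_profile(g)
        nbar[g] = prof.n_bar
        if prof.n_bar <= 0:
            empty[g] = True
        else:
            psp[g] = psi_sp(prof)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    pz[g] = psi_z(prof)
                except ValueError:
                    pz[g] = np.nan
        # accuracy
        vals = []
        for rep in groups:
            bs = np.flatnonzero(family.repeat_of == rep)
            if az_aggregation == "pooled":
                s = np.concatenate([family.scores[g][b] for b in bs])
                t = np.concatenate([y[family.test_indices[b]] for b in bs])
                vals.append(auc(s, t))
            else:
                for b in bs:
                    t = y[family.test_indices[b]]
                    if np.unique(t).size == 2:
                        vals.append(auc(family.scores[g][b], t))
        Az[g] = float(np.mean(vals)) if vals else np.nan
    return GridSummary(lambda1=grid.lambda1, lambda2=grid.lambda2,
                       Az=Az, psi_sp=psp, psi_z=pz, n_bar=nbar,
                       capped=family.capped.copy(), empty=empty)
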