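"""Permutation-calibrated significance for summary and voxel statistics.

Two levels of inference are supported, both one-tailed (larger = more
signal):

* **Summary level.** For each label permutation the decoder grid is
  retrained and the *maximum* of a summary statistic (Az, psi_sp or psi_|z|)
  over all non-capped grid points is recorded. Taking the max over the grid
  makes the null account for the selection of a regularization setting.
  Pooled across permutations (and subjects, if any), empirical one-tailed
  thresholds are the ceil order statistic x_(ceil((1-alpha)(m+1))) of the
  sorted null sample.

* **Voxel level.** Under the null the classifier has no spatial prior, so
  per-voxel statistics are exchangeable and may be pooled across voxels: for
  each permutation the JointSP-selected model contributes the selection
  probabilities and |z|-scores of its v_i > 0 voxels. Observed voxel
  statistics are converted to add-one empirical p-values
  p = (1 + #{null >= obs}) / (1 + m) and thresholded by Benjamini-Hochberg
  FDR.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .metrics import GridSummary, SelectionProfile
from .selection import choose

__all__ = [
    "NullDistributions",
    "PermutationRun",
    "VoxelSignificance",
    "summary_null",
    "empirical_pvalue",
    "build_voxel_null",
    "fdr_bh",
    "voxel_significance",
]

SUMMARY_STATS = ("Az", "psi_sp", "psi_z")


@dataclass
class NullDistributions:
    """Pooled permutation null samples for voxel-level statistics."""

    voxel_null_sp: np.ndarray
    voxel_null_z: np.ndarray
    n_perm: int
    contributions: list = field(default_factory=list)  # voxels per permutation


@dataclass
class PermutationRun:
    """Output of one permutation pipeline run.

    ``profiles`` maps grid index -> SelectionProfile (a dict or a callable);
    only the JointSP-chosen point's profile is ever required.
    """

    summary: GridSummary
    profiles: Mapping[int, SelectionProfile] | Callable[[int], SelectionProfile]

    def profile_for(self, g: int) -> SelectionProfile:
        if callable(self.profiles):
            return self.profiles(g)
        return self.profiles[g]


@dataclass
class VoxelSignificance:
    """Voxel-level empirical p-values and FDR rejection masks."""

    tested: np.ndarray          # voxel indices with v_i > 0
    pvals_sp: np.ndarray
    pvals_z: np.ndarray
    reject_sp: np.ndarray       # boolean over tested voxels
    reject_z: np.ndarray
    alpha: float

    @property
    def n_tested(self) -> int:
        return self.tested.size

    def mask(self, n_voxels: int, which: str = "sp") -> np.ndarray:
        """Dense boolean significance mask over all voxels."""
        rej = self.reject_sp if which == "sp" else self.reject_z
        out = np.zeros(n_voxels, dtype=bool)
        out[self.tested[rej]] = True
        return out


def _threshold(sorted_null: np.ndarray, alpha: float) -> float:
    m = sorted_null.size
    k = int(np.ceil((1.0 - alpha) * (m + 1)))
    if k > m:
        warnings.warn(
            f"only {m} permutation values: the {1 - alpha:.0%} threshold is "
            "clipped to the sample maximum (anti-conservative)", stacklevel=3)
        k = m
    return float(sorted_null[k - 1])


def summary_null(perm_summaries: Sequence[GridSummary], statistic: str,
                 alphas: Sequence[float] = (0.05, 0.01),
                 ) -> tuple[np.ndarray, dict]:
    """Max-over-grid null sample and one-tailed thresholds for a statistic.

    For each permutation's grid summary the maximum of ``statistic`` over
    all eligible (non-capped, non-empty) grid points enters the pooled null.
    Thresholds are empirical (1-alpha) quantiles (ceil order statistic).
    """
    if statistic not in SUMMARY_STATS:
        raise ValueError(f"statistic must be one of {SUMMARY_STATS}")
    if len(perm_summaries) == 0:
        raise ValueError("empty permutation set")
    vals = []
    for s in perm_summaries:
        stat = getattr(s, statistic)
        ok = s.eligible & np.isfinite(stat)
        if ok.any():
            vals.append(float(stat[ok].max()))
    null = np.sort(np.asarray(vals))
    if null.size < 20:
        warnings.warn(
            f"{null.size} permutations is below the ~20 needed for a "
            "p<0.05 threshold", stacklevel=2)
    thresholds = {a: _threshold(null, a) for a in alphas}
    return null, thresholds


def empirical_pvalue(observed, null_sample: np.ndarray):
    """One-tailed upper add-one p-value(s): (1 + #{null >= obs}) / (1 + m).

    Accepts a scalar or a vector of observed values; ties in the null sample
    count toward the >= (conservative).
    """
    null = np.sort(np.asarray(null_sample, dtype=float))
    m = null.size
    if m == 0:
        raise ValueError("null sample is empty")
    obs = np.asarray(observed, dtype=float)
    n_ge = m - np.searchsorted(null, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + m)
    return float(p) if np.isscalar(observed) or obs.ndim == 0 else p


def build_voxel_null(perm_runs: Sequence[PermutationRun]) -> NullDistributions:
    """Pool voxel-level null statistics across permutation runs.

    For each run the best model is selected by JointSP; the selection
    probabilities and finite |z|-scores of its v_i > 0 voxels are pooled
    across all runs. Runs whose chosen model selects no voxels contribute
    nothing (logged via a warning counter).
    """
    sp_parts, z_parts, contrib = [], [], []
    n_empty = 0
    for run in perm_runs:
        try:
            g = choose(run.summary, "JointSP")
        except ValueError:
            n_empty += 1
            contrib.append(0)
            continue
        prof = run.profile_for(g)
        sel = prof.v > 0
        if not sel.any():
            n_empty += 1
            contrib.append(0)
            continue
        sp_parts.append(prof.v[sel])
        absz = np.abs(prof.z[sel])
        z_parts.append(absz[np.isfinite(absz)])
        contrib.append(int(sel.sum()))
    if n_empty:
        warnings.warn(f"{n_empty} permutation(s) selected no voxels and "
                      "contributed nothing to the voxel null", stacklevel=2)
    if not sp_parts:
        raise ValueError(
            "every permutation selected zero voxels: the voxel-level null "
            "distribution is empty; increase n_perm or loosen the grid")
    return NullDistributions(
        voxel_null_sp=np.concatenate(sp_parts),
        voxel_null_z=np.concatenate(z_parts) if z_parts else np.empty(0),
        n_perm=len(perm_runs), contributions=contrib)


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05,
           ) -> tuple[np.ndarray, int]:
    """Benjamini-Hochberg step-up procedure.

    Sorts the N p-values ascending, finds the largest rank k with
    p_(k) <= (k / N) * alpha, and rejects the k smallest; k = 0 rejects
    none. Returns (reject mask in the original order, k).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    N = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ok = ranked <= (np.arange(1, N + 1) / N) * alpha
    k = int(np.flatnonzero(ok).max() + 1) if ok.any() else 0
    reject = np.zeros(N, dtype=bool)
    reject[order[:k]] = True
    return reject, k


def voxel_significance(profile: SelectionProfile, nulls: NullDistributions,
                       alpha: float = 0.05) -> VoxelSignificance:
    """FDR-thresholded voxel-level significance of an observed brain map.

    Tests every voxel with v_i > 0 against the pooled permutation nulls,
    separately for the selection-probability and |z|-score statistics. An
    infinite observed |z| (zero weight SE across resamples) exceeds every
    finite null value and so attains the minimum add-one p-value.
    """
    tested = np.flatnonzero(profile.v > 0)
    if tested.size == 0:
        raise ValueError("observed model selects no voxels; nothing to test")
    p_sp = empirical_pvalue(profile.v[tested], nulls.voxel_null_sp)
    if nulls.voxel_null_z.size:
        p_z = empirical_pvalue(np.abs(profile.z[tested]), nulls.voxel_null_z)
    else:
        p_z = np.ones(tested.size)
    rej_sp, _ = fdr_bh(p_sp, alpha)
    rej_z, _ = fdr_bh(p_z, alpha)
    return VoxelSignificance(tested=tested, pvals_sp=np.atleast_1d(p_sp),
                             pvals_z=np.atleast_1d(p_z),
                             reject_sp=rej_sp, reject_z=rej_z, alpha=alpha)
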