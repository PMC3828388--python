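"""LS-S ("least squares – separate") per-trial deconvolution.

Rapid event-related designs with 2–3 s inter-trial intervals produce heavily
overlapping BOLD responses. LS-S un-mixes them by fitting, for every trial
separately, a GLM with two task regressors: a *signal* regressor (the HRF
response of that trial alone) and a *noise* regressor (the superimposed HRF
responses of every other trial). The fitted signal coefficient is that
trial's activation estimate. Only trial timing enters — never the labels —
so the step sits safely outside cross-validation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialDataset
from .hrf import HRFParams, trial_regressor

__all__ = ["TrialRegressorPair", "build_trial_regressors", "lss_betas"]


@dataclass(frozen=True)
class TrialRegressorPair:
    """Signal/noise regressor pair for one trial, sampled on the TR grid."""

    signal: np.ndarray
    noise: np.ndarray


def _all_regressors(onsets: np.ndarray, tr: float, n_frames: int,
                    hrf: HRFParams, durations: np.ndarray | None) -> np.ndarray:
    frame_times = np.arange(n_frames) * tr
    cols = []
    for i, onset in enumerate(onsets):
        dur = 0.0 if durations is None else float(durations[i])
        cols.append(trial_regressor(float(onset), frame_times, hrf, dur))
    return np.column_stack(cols)


def build_trial_regressors(events: pd.DataFrame, t: int, tr: float,
                           n_frames: int, hrf: HRFParams = HRFParams(),
                           use_duration: bool = False) -> TrialRegressorPair:
    """Signal and noise regressors for trial ``t``.

    ``signal`` is the onset impulse of trial ``t`` convolved with the
    canonical HRF; ``noise`` is the linear superposition of all other trials'
    responses. With ``use_duration=True`` events are modelled as boxcars of
    their tabulated duration instead of impulses.
    """
    onsets = np.asarray(events["onset_s"], dtype=float)
    if not 0 <= t < onsets.size:
        raise IndexError(f"trial index {t} out of range [0, {onsets.size})")
    if onsets.min() < 0 or onsets.max() >= n_frames * tr:
        raise ValueError("event onsets must lie within the acquisition window")
    durations = (np.asarray(events["duration_s"], dtype=float)
                 if use_duration else None)
    R = _all_regressors(onsets, tr, n_frames, hrf, durations)
    signal = R[:, t]
    noise = np.delete(R, t, axis=1).sum(axis=1)
    return TrialRegressorPair(signal=signal, noise=noise)


def lss_betas(series: np.ndarray, events: pd.DataFrame, tr: float,
              hrf: HRFParams = HRFParams(), use_duration: bool = False,
              confounds: np.ndarray | None = None,
              grid_shape: tuple[int, int, int] | None = None) -> TrialDataset:
    """Estimate one activation per trial per voxel by LS-S regression.

    For each trial the design is [signal, noise, intercept] (the noise column
    is dropped in a single-trial experiment, where it is identically zero);
    user-supplied ``confounds`` columns are appended unpenalised. Returns a
    :class:`TrialDataset` whose ``X`` holds the signal coefficients and whose
    labels are passed through from the event table.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    if not np.isfinite(series).all():
        raise ValueError("time series contains non-finite values")
    n_frames, n_voxels = series.shape
    onsets = np.asarray(events["onset_s"], dtype=float)
    n_trials = onsets.size
    if n_trials < 1:
        raise ValueError("need at least one trial")
    durations = (np.asarray(events["duration_s"], dtype=float)
                 if use_duration else None)
    R = _all_regressors(onsets, tr, n_frames, hrf, durations)
    total = R.sum(axis=1)
    intercept = np.ones(n_frames)
    betas = np.empty((n_trials, n_voxels))
    for t in range(n_trials):
        signal = R[:, t]
        noise = total - signal
        cols = [signal] if np.allclose(noise, 0.0) else [signal, noise]
        cols.append(intercept)
        if confounds is not None:
            cols.extend(np.asarray(confounds, dtype=float).T)
        D = np.column_stack(cols)
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient LS-S design at trial {t} "
                "(identical or degenerate onsets?)"
            )
        coef, *_ = np.linalg.lstsq(D, series, rcond=None)
        betas[t] = coef[0]
    labels = np.asarray(events["label"])
    if grid_shape is None:
        grid_shape = (n_voxels, 1, 1)
    return TrialDataset(X=betas, y=labels, grid_shape=grid_shape)
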