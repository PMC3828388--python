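"""Canonical haemodynamic response function and event regressors.

The canonical HRF is the standard double-gamma: a positive gamma density
peaking ~6 s after stimulus onset minus a scaled-down gamma undershoot
peaking ~16 s, truncated at 32 s and normalised to unit peak amplitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (all times in seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 6.0  # peak-to-undershoot amplitude ratio
    length: float = 32.0


def hrf_curve(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    Zero for t < 0 and t >= ``params.length``; peak amplitude normalised to 1.
    """
    t = np.asarray(t, dtype=float)
    # gamma densities parameterised so the mode sits at the stated delay
    a1 = params.peak_delay / params.peak_disp + 1.0
    a2 = params.undershoot_delay / params.undershoot_disp + 1.0

    def _dg(tt):
        return (stats.gamma.pdf(tt, a1, scale=params.peak_disp)
                - stats.gamma.pdf(tt, a2, scale=params.undershoot_disp)
                / params.undershoot_ratio)

    h = np.where((t >= 0) & (t < params.length), _dg(t), 0.0)
    # normalise to unit peak on a fine grid (stable w.r.t. the sampling of t)
    return h / _dg(np.arange(0.0, params.length, 0.01)).max()


def trial_regressor(onset: float, frame_times: np.ndarray,
                    params: HRFParams = HRFParams(),
                    duration: float = 0.0) -> np.ndarray:
    """Expected BOLD regressor for a single event sampled at ``frame_times``.

    ``duration=0`` models the event as an impulse (a shifted HRF); a positive
    duration models a boxcar convolved with the HRF on a fine (10 ms) grid.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if duration <= 0:
        return hrf_curve(frame_times - onset, params)
    dt = 0.01
    tf = np.arange(0.0, frame_times.max() + dt, dt)
    box = ((tf >= onset) & (tf < onset + duration)).astype(float)
    h = hrf_curve(np.arange(0.0, params.length, dt), params)
    conv = np.convolve(box, h)[: tf.size] * dt / duration
    return np.interp(frame_times, tf, conv, left=0.0, right=0.0)
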