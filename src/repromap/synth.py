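"""Synthetic data emulating a rapid event-related oddball decoding experiment.

Two generators are provided, matching the two entry points of the pipeline:

* :func:`make_trial_dataset` draws trial-wise activation matrices directly —
  rare targets (probability ~0.2) against standards, with a small set of
  spatially clustered signal voxels carrying a class-conditional mean shift
  among many null voxels.
* :func:`make_timeseries_dataset` builds voxel time series by linear
  superposition of HRF-convolved trial responses with 2–3 s jittered
  inter-trial intervals at a 2 s TR, the regime in which single-trial
  responses overlap and LS-S deconvolution is required.

Noise is i.i.d. Gaussian by default; the time-series generator exposes an
AR(1) knob because real BOLD noise is temporally autocorrelated. Ground truth
(signal voxel indices, generating amplitudes) is always returned so that
recovery can be scored exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialDataset
from .hrf import HRFParams, trial_regressor

__all__ = [
    "SyntheticSpec",
    "TimeSeriesSpec",
    "make_trial_dataset",
    "make_timeseries_dataset",
]


class GeometryError(ValueError):
    """Requested signal clusters cannot be placed on the voxel grid."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of a synthetic trial-wise activation dataset.

    ``effect_size`` is the standardized class-mean difference (Cohen's d) at
    each signal voxel; ``target_prob`` is the per-trial probability of the
    rare (target) class. Signal voxels form ``n_signal_clusters``
    face-connected blobs on the 3-D grid.
    """

    n_trials: int = 300
    n_voxels: int = 2000
    grid_shape: tuple[int, int, int] = (20, 10, 10)
    n_signal_voxels: int = 50
    n_signal_clusters: int = 5
    effect_size: float = 1.0
    noise_sd: float = 1.0
    target_prob: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_signal_voxels > self.n_voxels:
            raise ValueError("n_signal_voxels exceeds n_voxels")
        if not 0.0 < self.target_prob < 1.0:
            raise ValueError("target_prob must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if int(np.prod(self.grid_shape)) < self.n_voxels:
            raise ValueError("grid_shape product must be >= n_voxels")
        if self.n_signal_voxels > 0 and self.n_signal_clusters < 1:
            raise ValueError("need at least one cluster for signal voxels")
        if 0 < self.n_signal_voxels < self.n_signal_clusters:
            raise ValueError("fewer signal voxels than clusters")


def _face_neighbors(idx: int, shape: tuple[int, int, int]) -> list[int]:
    x, y, z = np.unravel_index(idx, shape)
    out = []
    for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        nx, ny, nz = x + dx, y + dy, z + dz
        if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
            out.append(int(np.ravel_multi_index((nx, ny, nz), shape)))
    return out


def _grow_clusters(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Place signal clusters by random face-neighbor accretion.

    Blobs are kept mutually non-adjacent so that the signal support has
    exactly ``n_signal_clusters`` face-connected components. Returns flat
    grid indices (all < n_voxels, i.e. inside the voxel mask).
    """
    if spec.n_signal_voxels == 0:
        return np.empty(0, dtype=np.int64)
    sizes = np.full(spec.n_signal_clusters,
                    spec.n_signal_voxels // spec.n_signal_clusters)
    sizes[: spec.n_signal_voxels % spec.n_signal_clusters] += 1
    in_mask = lambda j: j < spec.n_voxels  # noqa: E731

    for _restart in range(20):
        taken: set[int] = set()       # cluster members
        forbidden: set[int] = set()   # members plus their face neighbors
        clusters: list[list[int]] = []
        ok = True
        for size in sizes:
            placed = False
            for _attempt in range(200):
                seed_vox = int(rng.integers(spec.n_voxels))
                if seed_vox in forbidden:
                    continue
                blob = [seed_vox]
                frontier = [
                    j for j in _face_neighbors(seed_vox, spec.grid_shape)
                    if in_mask(j) and j not in forbidden
                ]
                while len(blob) < size and frontier:
                    j = frontier.pop(int(rng.integers(len(frontier))))
                    if j in forbidden or j in blob:
                        continue
                    blob.append(j)
                    frontier.extend(
                        k for k in _face_neighbors(j, spec.grid_shape)
                        if in_mask(k) and k not in forbidden and k not in blob
                    )
                if len(blob) == size:
                    clusters.append(blob)
                    taken.update(blob)
                    forbidden.update(blob)
                    for v in blob:
                        forbidden.update(
                            k for k in _face_neighbors(v, spec.grid_shape))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.sort(np.concatenate([np.array(c) for c in clusters]))
    raise GeometryError(
        f"could not place {spec.n_signal_clusters} non-adjacent cluster(s) "
        f"totalling {spec.n_signal_voxels} voxels on grid {spec.grid_shape} "
        f"with {spec.n_voxels} in-mask voxels"
    )


def make_trial_dataset(spec: SyntheticSpec) -> tuple[TrialDataset, np.ndarray]:
    """Generate a trial-wise activation dataset with known signal voxels.

    Labels are i.i.d. Bernoulli(``target_prob``); null voxels are
    Normal(0, noise_sd²); signal voxels additionally receive a mean shift of
    ``effect_size * noise_sd`` on target trials. Returns the dataset and the
    ground-truth signal voxel (column) indices.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    signal_idx = _grow_clusters(spec, rng)
    y = rng.binomial(1, spec.target_prob, size=spec.n_trials).astype(np.int8)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_trials, spec.n_voxels))
    if signal_idx.size and spec.effect_size > 0:
        X[np.ix_(y == 1, signal_idx)] += spec.effect_size * spec.noise_sd
    ds = TrialDataset(X=X, y=y, grid_shape=spec.grid_shape)
    return ds, signal_idx


@dataclass(frozen=True)
class TimeSeriesSpec:
    """Design of a synthetic BOLD time-series experiment.

    Onset-to-onset spacing is ``stim_duration`` plus a uniform draw from
    ``iti_range``; each voxel's series is the sum over trials of the trial
    amplitude times the HRF-convolved onset impulse, sampled at ``TR``,
    plus Gaussian (optionally AR(1)) noise.
    """

    TR: float = 2.0
    n_trials_per_class: tuple[int, int] = (300, 75)
    iti_range: tuple[float, float] = (2.0, 3.0)
    stim_duration: float = 0.2
    hrf_params: HRFParams = field(default_factory=HRFParams)
    amplitudes: np.ndarray | None = None  # (n_trials, n_voxels) true betas
    noise_sd: float = 0.0
    ar1_rho: float = 0.0
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return int(sum(self.n_trials_per_class))

    def validate(self) -> None:
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        if self.iti_range[0] > self.iti_range[1]:
            raise ValueError("iti_range min must be <= max")
        if min(self.n_trials_per_class) < 0:
            raise ValueError("trial counts must be non-negative")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.amplitudes is not None:
            amp = np.asarray(self.amplitudes)
            if amp.ndim != 2 or amp.shape[0] != self.n_trials:
                raise ValueError("amplitudes must be (n_trials, n_voxels)")


def make_timeseries_dataset(
    spec: TimeSeriesSpec,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Generate voxel time series, an event table, and the true amplitudes.

    Returns ``(series, events, true_betas)`` where ``series`` is
    (n_frames, n_voxels), ``events`` has columns ``onset_s``, ``duration_s``,
    ``label`` with strictly increasing onsets, and ``true_betas`` is the
    (n_trials, n_voxels) amplitude matrix used for generation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_trials_per_class
    labels = np.concatenate([np.zeros(n0, dtype=np.int8),
                             np.ones(n1, dtype=np.int8)])
    rng.shuffle(labels)
    n_trials = labels.size
    gaps = spec.stim_duration + rng.uniform(*spec.iti_range, size=n_trials)
    onsets = np.cumsum(gaps) - gaps[0] + spec.iti_range[0]
    if spec.amplitudes is None:
        betas = np.ones((n_trials, 1))
    else:
        betas = np.asarray(spec.amplitudes, dtype=float)
    n_voxels = betas.shape[1]
    n_frames = int(np.ceil((onsets[-1] + spec.hrf_params.length) / spec.TR))
    frame_times = np.arange(n_frames) * spec.TR
    R = np.column_stack([trial_regressor(o, frame_times, spec.hrf_params)
                         for o in onsets])
    series = R @ betas
    if spec.noise_sd > 0:
        eps = rng.normal(0.0, spec.noise_sd, size=series.shape)
        if spec.ar1_rho > 0:
            for t in range(1, n_frames):
                eps[t] = spec.ar1_rho * eps[t - 1] + \
                    np.sqrt(1 - spec.ar1_rho ** 2) * eps[t]
        series = series + eps
    events = pd.DataFrame({
        "onset_s": onsets,
        "duration_s": np.full(n_trials, spec.stim_duration),
        "label": labels,
    })
    return series, events, betas
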