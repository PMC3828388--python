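"""Core in-memory containers shared across the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _default_affine() -> np.ndarray:
    return np.eye(4)


@dataclass
class TrialDataset:
    """Trial-by-voxel activation matrix with binary labels and voxel-grid geometry.

    Parameters
    ----------
    X : (n_trials, n_voxels) float array
        One activation estimate per trial per voxel (e.g. LS-S betas).
    y : (n_trials,) int array
        Binary labels, 0 = standard, 1 = target/oddball.
    grid_shape : 3-tuple of int
        Dimensions of the voxel grid the columns of ``X`` live on.
    voxel_indices : (n_voxels,) int array, optional
        Flat (C-order) index into ``grid_shape`` for each column. Defaults to
        the first ``n_voxels`` positions of the grid.
    affine : (4, 4) array
        Voxel-to-world affine used when writing NIfTI volumes.
    """

    X: np.ndarray
    y: np.ndarray
    grid_shape: tuple[int, int, int]
    voxel_indices: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trials x voxels)")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError(
                f"label vector length {self.y.shape} does not match "
                f"{self.X.shape[0]} trials"
            )
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("labels must be binary (0/1)")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3-D")
        n_grid = int(np.prod(self.grid_shape))
        if self.voxel_indices is None:
            self.voxel_indices = np.arange(self.n_voxels)
        else:
            self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.int64)
        if self.voxel_indices.shape != (self.n_voxels,):
            raise ValueError("voxel_indices must have one entry per voxel")
        if n_grid < self.n_voxels:
            raise ValueError("grid too small for the number of voxels")
        if self.voxel_indices.max(initial=-1) >= n_grid:
            raise ValueError("voxel index outside the grid")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector back into a dense 3-D grid volume."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError("values must have one entry per voxel")
        vol = np.full(int(np.prod(self.grid_shape)), fill, dtype=float)
        vol[self.voxel_indices] = values
        return vol.reshape(self.grid_shape)
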