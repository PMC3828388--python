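"""Group-level aggregation of per-subject significance masks.

Subject masks (already resampled to a common voxel grid upstream) are summed
so each voxel's value is the number of subjects declaring it significant;
the suprathreshold set is then decomposed into connected clusters and each
cluster is reported with its size, the number of distinct contributing
subjects, the maximum per-voxel subject count, and its centroid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["Cluster", "sum_masks", "cluster_mask", "clusters_to_frame"]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class Cluster:
    """One connected component of the group count map."""

    voxels: np.ndarray          # (k, 3) voxel coordinates
    size: int
    max_subjects_per_voxel: int
    total_subjects: int | None  # distinct subjects contributing >= 1 voxel
    centroid: tuple[float, float, float]


def sum_masks(masks) -> np.ndarray:
    """Voxelwise integer sum of binary 3-D masks on a shared grid."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    shape = np.asarray(masks[0]).shape
    counts = np.zeros(shape, dtype=np.int32)
    for s, m in enumerate(masks):
        m = np.asarray(m)
        if m.shape != shape:
            raise ValueError(
                f"mask for subject {s} has shape {m.shape}, expected {shape}")
        counts += (m != 0).astype(np.int32)
    return counts


def cluster_mask(counts: np.ndarray, masks=None,
                 connectivity: int = 26) -> list[Cluster]:
    """Connected components of {count > 0}, sorted by size descending.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full neighbour
    cube, the default). ``total_subjects`` requires the original per-subject
    masks and is None otherwise. Ties in size are broken by first voxel
    position for determinism.
    """
    counts = np.asarray(counts)
    if counts.ndim != 3:
        raise ValueError("counts must be a 3-D volume")
    if counts.min(initial=0) < 0:
        raise ValueError("counts must be non-negative")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_clusters = ndimage.label(counts > 0, structure=structure)
    clusters = []
    for lab in range(1, n_clusters + 1):
        sel = labels == lab
        coords = np.argwhere(sel)
        total = None
        if masks is not None:
            total = int(sum(bool((np.asarray(m) != 0)[sel].any())
                            for m in masks))
        clusters.append(Cluster(
            voxels=coords,
            size=int(sel.sum()),
            max_subjects_per_voxel=int(counts[sel].max()),
            total_subjects=total,
            centroid=tuple(coords.mean(axis=0)),
        ))
    clusters.sort(key=lambda c: (-c.size, tuple(c.voxels[0])))
    return clusters


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster table: one row per cluster, largest first."""
    return pd.DataFrame({
        "cluster_id": np.arange(1, len(clusters) + 1),
        "size": [c.size for c in clusters],
        "total_subjects": [c.total_subjects for c in clusters],
        "max_subj_per_voxel": [c.max_subjects_per_voxel for c in clusters],
        "centroid_x": [c.centroid[0] for c in clusters],
        "centroid_y": [c.centroid[1] for c in clusters],
        "centroid_z": [c.centroid[2] for c in clusters],
    })
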