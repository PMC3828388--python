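"""Reading and writing the pipeline's on-disk formats.

Volumes and masks are NIfTI-1 (via nibabel); tables are TSV/CSV (pandas);
configuration and reports are JSON. Trial datasets round-trip as a 4-D NIfTI
(trials along the 4th dimension) plus a labels TSV.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .data import TrialDataset
from .metrics import SelectionProfile

__all__ = [
    "save_trial_dataset", "load_trial_dataset",
    "save_events", "load_events",
    "save_mask", "load_mask",
    "save_profile_volumes", "save_family", "load_family_weights",
    "save_plan", "write_json", "read_json",
]


def save_trial_dataset(ds: TrialDataset, out_dir) -> None:
    """Write a trial dataset as 4-D NIfTI + labels TSV (+ voxel index TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol4 = np.zeros(ds.grid_shape + (ds.n_trials,), dtype=np.float64)
    flat = vol4.reshape(-1, ds.n_trials)
    flat[ds.voxel_indices] = ds.X.T
    nib.save(nib.Nifti1Image(vol4, ds.affine), out_dir / "trials.nii")
    pd.DataFrame({"trial_index": np.arange(ds.n_trials),
                  "label": ds.y}).to_csv(
        out_dir / "labels.tsv", sep="\t", index=False)
    pd.DataFrame({"voxel_index": ds.voxel_indices}).to_csv(
        out_dir / "voxels.tsv", sep="\t", index=False)


def load_trial_dataset(in_dir) -> TrialDataset:
    in_dir = Path(in_dir)
    img = nib.load(in_dir / "trials.nii")
    vol4 = np.asarray(img.dataobj, dtype=np.float64)
    if vol4.ndim != 4:
        raise ValueError("trials.nii must be a 4-D volume (trials 4th dim)")
    labels = pd.read_csv(in_dir / "labels.tsv", sep="\t")
    for col in ("trial_index", "label"):
        if col not in labels.columns:
            raise ValueError(f"labels.tsv is missing required column {col!r}")
    if labels["label"].isna().any():
        row = int(labels.index[labels["label"].isna()][0])
        raise ValueError(f"labels.tsv has a missing label at row {row}")
    if len(labels) != vol4.shape[3]:
        raise ValueError(
            f"labels.tsv has {len(labels)} rows but trials.nii holds "
            f"{vol4.shape[3]} trials")
    vox_path = in_dir / "voxels.tsv"
    if vox_path.exists():
        voxel_indices = pd.read_csv(vox_path, sep="\t")["voxel_index"].to_numpy()
    else:
        voxel_indices = np.arange(int(np.prod(vol4.shape[:3])))
    X = vol4.reshape(-1, vol4.shape[3])[voxel_indices].T
    return TrialDataset(X=X, y=labels["label"].to_numpy(),
                        grid_shape=vol4.shape[:3],
                        voxel_indices=voxel_indices, affine=img.affine)


def save_events(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    for col in ("onset_s", "label"):
        if col not in events.columns:
            raise ValueError(f"events table is missing required column {col!r}")
    if events["label"].isna().any():
        row = int(events.index[events["label"].isna()][0])
        raise ValueError(f"events table has a missing label at row {row}")
    if "duration_s" not in events.columns:
        events = events.assign(duration_s=0.0)
    return events


def save_mask(mask3d: np.ndarray, path, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(mask3d, dtype=np.uint8), affine), path)


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj) != 0


def save_profile_volumes(profile: SelectionProfile, ds: TrialDataset,
                         out_dir, prefix: str = "profile") -> None:
    """Write the v / mu / se / z maps of a selection profile as NIfTI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, vec in (("v", profile.v), ("mu", profile.mu),
                      ("se", profile.se), ("z", profile.z)):
        vol = ds.to_volume(np.nan_to_num(vec, posinf=0.0, neginf=0.0))
        nib.save(nib.Nifti1Image(vol, ds.affine),
                 out_dir / f"{prefix}_{name}.nii")


def save_family(family, out_dir) -> None:
    """Serialize a classifier family as a sparse weight table + metadata.

    ``weights.tsv`` holds one row per nonzero weight (grid_point, resample,
    voxel_index, weight); ``intercepts.tsv`` one row per fitted
    (grid_point, resample); ``family.json`` the grid, cap and shape
    metadata.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    intercepts = []
    for g in range(family.grid.n_points):
        for b, entry in enumerate(family.weights[g]):
            if entry is None:
                continue
            idx, val, intercept = entry
            intercepts.append((g, b, intercept))
            for i, w in zip(idx, val):
                rows.append((g, b, int(i), float(w)))
    pd.DataFrame(rows, columns=["grid_point", "resample", "voxel_index",
                                "weight"]).to_csv(
        out_dir / "weights.tsv", sep="\t", index=False)
    pd.DataFrame(intercepts, columns=["grid_point", "resample",
                                      "intercept"]).to_csv(
        out_dir / "intercepts.tsv", sep="\t", index=False)
    write_json({
        "n_voxels": family.n_voxels,
        "B": family.B,
        "max_voxels": family.max_voxels,
        "capped": family.capped,
        "lambda2_values": family.grid.lambda2_values,
        "lambda1_paths": family.grid.lambda1_paths,
    }, out_dir / "family.json")


def load_family_weights(in_dir):
    """Read a serialized family back as dense per-(grid point, resample)
    sparse maps: {(g, b): (indices, weights)} plus the metadata dict."""
    in_dir = Path(in_dir)
    meta = read_json(in_dir / "family.json")
    table = pd.read_csv(in_dir / "weights.tsv", sep="\t")
    maps = {}
    for (g, b), sub in table.groupby(["grid_point", "resample"]):
        maps[(int(g), int(b))] = (sub["voxel_index"].to_numpy(),
                                  sub["weight"].to_numpy())
    return maps, meta


def save_plan(plan, out_dir) -> None:
    """Serialize a resampling plan (TSV assignment table + JSON metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if plan.kind == "cv":
        np.savetxt(out_dir / "assignments.tsv", plan.fold_ids,
                   fmt="%d", delimiter="\t")
    elif plan.kind == "permutation":
        np.savetxt(out_dir / "assignments.tsv", plan.labels,
                   fmt="%d", delimiter="\t")
    else:
        np.savetxt(out_dir / "assignments.tsv", plan.indices,
                   fmt="%d", delimiter="\t")
    write_json({"kind": plan.kind, "n": plan.n, "seed": plan.seed,
                "n_folds": plan.n_folds, "n_repeats": plan.n_repeats},
               out_dir / "plan.json")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
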