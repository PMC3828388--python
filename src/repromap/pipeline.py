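"""End-to-end orchestration: train -> summarize -> select ->
permutation-calibrate -> voxel FDR.

All randomness is funnelled through named seed streams derived from
``RunConfig.seed``, so reruns with the same configuration are deterministic
and every written artifact embeds the configuration hash.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data import TrialDataset
from .enet import (ClassifierFamily, RegGrid, default_grid,
                   fit_grid_family, make_design_cache)
from .metrics import GridSummary, SelectionProfile, summarize_grid
from .resampling import make_cv_plan, make_permutations
from .selection import SelectionResult, select_models
from .significance import (NullDistributions, PermutationRun,
                           VoxelSignificance, build_voxel_null, summary_null,
                           voxel_significance)

logger = logging.getLogger("repromap")

__all__ = ["RunConfig", "PipelineResult", "run_analysis", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a single-subject decoding analysis."""

    n_folds: int = 10
    n_repeats: int = 10
    n_perm: int = 100
    n_lambda1: int = 100
    n_lambda2: int = 11
    lambda1_ratio: float = 0.1
    lambda2_ratios: tuple[float, float] = (1e-3, 1.0)
    max_voxels: int = 1000
    alphas: tuple[float, float] = (0.05, 0.01)
    fdr_alpha: float = 0.05
    strategy: str = "JointSP"
    standardize: bool = True
    stratified: bool = True
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything a single-subject run produces."""

    config: RunConfig
    summary: GridSummary
    selection: SelectionResult
    chosen_profile: SelectionProfile
    family: ClassifierFamily | None = None
    perm_summaries: list = field(default_factory=list)
    summary_nulls: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    voxel_nulls: NullDistributions | None = None
    voxel_sig: VoxelSignificance | None = None
    sig_mask_sp: np.ndarray | None = None
    sig_mask_z: np.ndarray | None = None
    timings: dict = field(default_factory=dict)


def run_analysis(ds: TrialDataset, config: RunConfig,
                 grid: RegGrid | None = None,
                 keep_family: bool = False) -> PipelineResult:
    """Run the full single-subject analysis on an in-memory dataset.

    With ``config.n_perm == 0`` the pipeline completes through model
    selection and the significance stages are skipped with a notice.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    if grid is None:
        grid = default_grid(ds.X, ds.y, standardize=config.standardize,
                            n_lambda1=config.n_lambda1,
                            n_lambda2=config.n_lambda2,
                            lambda1_ratio=config.lambda1_ratio,
                            lambda2_ratios=config.lambda2_ratios)
    plan = make_cv_plan(ds.n_trials, config.n_folds, config.n_repeats,
                        seed=config.seed, stratified=config.stratified,
                        y=ds.y)
    cache = make_design_cache(ds.X, plan, standardize=config.standardize)
    family = fit_grid_family(ds.X, ds.y, grid, plan,
                             max_voxels=config.max_voxels,
                             standardize=config.standardize, cache=cache)
    summary = summarize_grid(family)
    selection = select_models(summary)
    chosen = selection.chosen[config.strategy]
    chosen_profile = family.selection_profile(chosen)
    timings["train_and_select"] = time.perf_counter() - t0

    result = PipelineResult(config=config, summary=summary,
                            selection=selection,
                            chosen_profile=chosen_profile,
                            family=family if keep_family else None,
                            timings=timings)
    if config.n_perm == 0:
        logger.info("n_perm=0: significance stages skipped")
        return result

    t1 = time.perf_counter()
    perms = make_permutations(ds.y, config.n_perm, seed=config.seed)
    perm_summaries: list[GridSummary] = []
    perm_runs: list[PermutationRun] = []
    for i in range(config.n_perm):
        fam_i = fit_grid_family(ds.X, perms.labels[i], grid, plan,
                                max_voxels=config.max_voxels,
                                standardize=config.standardize,
                                cache=cache)
        summ_i = summarize_grid(fam_i)
        perm_summaries.append(summ_i)
        # materialise only the JointSP-chosen profile before the family dies
        profiles: dict[int, SelectionProfile] = {}
        try:
            from .selection import choose
            g_i = choose(summ_i, "JointSP")
            profiles[g_i] = fam_i.selection_profile(g_i)
        except ValueError:
            pass
        perm_runs.append(PermutationRun(summary=summ_i, profiles=profiles))
    timings["permutations"] = time.perf_counter() - t1

    result.perm_summaries = perm_summaries
    for stat in ("Az", "psi_sp", "psi_z"):
        null, thr = summary_null(perm_summaries, stat, alphas=config.alphas)
        result.summary_nulls[stat] = null
        result.thresholds[stat] = thr
    try:
        result.voxel_nulls = build_voxel_null(perm_runs)
        result.voxel_sig = voxel_significance(
            chosen_profile, result.voxel_nulls, alpha=config.fdr_alpha)
    except ValueError as err:
        # a fully null dataset can leave nothing to test (the chosen model
        # or every permutation model selects no voxels)
        logger.info("voxel-level significance skipped: %s", err)
        result.voxel_sig = None
    if result.voxel_sig is not None:
        result.sig_mask_sp = ds.to_volume(
            result.voxel_sig.mask(ds.n_voxels, "sp").astype(float)) > 0
        result.sig_mask_z = ds.to_volume(
            result.voxel_sig.mask(ds.n_voxels, "z").astype(float)) > 0
    timings["total"] = time.perf_counter() - t0
    result.timings = timings
    return result


def write_results(result: PipelineResult, ds: TrialDataset, out_dir) -> None:
    """Persist a run: summary CSV, selection JSON, nulls, masks, manifest."""
    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = result.config.config_hash()
    df = result.summary.to_frame()
    df.insert(0, "config_hash", chash)
    df.to_csv(out / "grid_summary.csv", index=False, float_format="%.17g")
    sel = {
        "config_hash": chash,
        "chosen": {k: int(v) for k, v in result.selection.chosen.items()},
        "pareto_indices": result.selection.pareto_indices,
        "hull_indices": result.selection.hull_indices,
        "thresholds": result.thresholds,
    }
    rio.write_json(sel, out / "selection.json")
    if result.summary_nulls:
        np.savetxt(out / "summary_nulls.csv",
                   np.column_stack([result.summary_nulls[s]
                                    for s in ("Az", "psi_sp", "psi_z")]),
                   delimiter=",", header="Az,psi_sp,psi_z", comments="")
    if result.voxel_sig is not None:
        rio.save_mask(result.sig_mask_sp, out / "sig_mask_sp.nii", ds.affine)
        rio.save_mask(result.sig_mask_z, out / "sig_mask_z.nii", ds.affine)
    rio.save_profile_volumes(result.chosen_profile, ds, out, prefix="chosen")
    thr = {stat: t[min(t)] for stat, t in result.thresholds.items()} or None
    from .selection import plot_tradeoff
    plot_tradeoff(result.summary, result.selection, thresholds=thr,
                  out_path=out / "tradeoff.png")
    rio.write_json({
        "config": asdict(result.config),
        "config_hash": chash,
        "version": __version__,
        "timings": result.timings,
    }, out / "manifest.json")


def run_pipeline(config: RunConfig, data_dir=None,
                 ds: TrialDataset | None = None) -> PipelineResult:
    """Load (or accept) a trial dataset, run the analysis, write outputs."""
    from . import io as rio

    if ds is None:
        if data_dir is None:
            raise ValueError("either ds or data_dir must be given")
        ds = rio.load_trial_dataset(data_dir)
    result = run_analysis(ds, config)
    if config.out_dir is not None:
        write_results(result, ds, config.out_dir)
    return result
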