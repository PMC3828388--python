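"""Deterministic, seedable resampling plans: CV partitions, label
permutations, and bootstrap replicates.

Every plan is generated from its own named RNG stream derived from the seed,
so e.g. requesting more permutations never perturbs the CV partition draws.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = ["ResamplePlan", "make_cv_plan", "make_permutations", "make_bootstrap"]


def _stream(seed: int, name: str) -> np.random.Generator:
    # one named child stream per plan kind
    ss = np.random.SeedSequence([int(seed), int.from_bytes(name.encode(), "little")])
    return np.random.default_rng(ss)


@dataclass
class ResamplePlan:
    """A fully materialised resampling plan.

    kind='cv'          : ``fold_ids`` is (n_repeats, n) with fold id per trial.
    kind='permutation' : ``labels`` is (n_perm, n) of permuted label vectors.
    kind='bootstrap'   : ``indices`` is (n_boot, n) in-bag index multisets and
                         ``oob`` the list of out-of-bag index arrays.
    """

    kind: str
    n: int
    seed: int
    n_folds: int = 0
    n_repeats: int = 0
    fold_ids: np.ndarray | None = None
    labels: np.ndarray | None = None
    indices: np.ndarray | None = None
    oob: list = field(default_factory=list)
    n_redrawn: int = 0

    @property
    def n_splits(self) -> int:
        """Total number of training sets B (cv: folds x repeats)."""
        if self.kind == "cv":
            return self.n_folds * self.n_repeats
        if self.kind == "bootstrap":
            return 0 if self.indices is None else self.indices.shape[0]
        return 0 if self.labels is None else self.labels.shape[0]

    def iter_splits(self):
        """Yield (repeat, fold, train_idx, test_idx) for every CV split."""
        if self.kind != "cv":
            raise ValueError("iter_splits is only defined for cv plans")
        all_idx = np.arange(self.n)
        for rep in range(self.n_repeats):
            ids = self.fold_ids[rep]
            for fold in range(self.n_folds):
                test = all_idx[ids == fold]
                train = all_idx[ids != fold]
                yield rep, fold, train, test


def make_cv_plan(n: int, k_folds: int, n_repeats: int, seed: int,
                 stratified: bool = True,
                 y: np.ndarray | None = None) -> ResamplePlan:
    """Repeated k-fold partition plan (stratified by default).

    With ``stratified=True`` a label vector ``y`` is required; class
    proportions are then balanced across folds, which matters at the ~0.2
    target rate of an oddball design.
    """
    if k_folds > n:
        raise ValueError("k_folds cannot exceed the number of trials")
    if stratified and y is None:
        raise ValueError("stratified folds require the label vector y")
    rng = _stream(seed, "cv")
    fold_ids = np.empty((n_repeats, n), dtype=np.int16)
    for rep in range(n_repeats):
        rs = int(rng.integers(2 ** 31 - 1))
        if stratified:
            splitter = StratifiedKFold(k_folds, shuffle=True, random_state=rs)
            splits = splitter.split(np.zeros(n), y)
        else:
            splitter = KFold(k_folds, shuffle=True, random_state=rs)
            splits = splitter.split(np.zeros(n))
        for fold, (_, test) in enumerate(splits):
            fold_ids[rep, test] = fold
    plan = ResamplePlan(kind="cv", n=n, seed=seed, n_folds=k_folds,
                        n_repeats=n_repeats, fold_ids=fold_ids)
    if not stratified and y is not None:
        y = np.asarray(y)
        for rep, fold, train, _ in plan.iter_splits():
            if np.unique(y[train]).size < 2:
                warnings.warn(
                    f"repeat {rep} fold {fold}: training split has one class",
                    stacklevel=2,
                )
    return plan


def make_permutations(y: np.ndarray, n_perm: int, seed: int) -> ResamplePlan:
    """Uniform random permutations of the label vector (class counts fixed)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y = np.asarray(y)
    rng = _stream(seed, "perm")
    labels = np.stack([rng.permutation(y) for _ in range(n_perm)])
    return ResamplePlan(kind="permutation", n=y.size, seed=seed, labels=labels)


def make_bootstrap(n: int, n_boot: int, seed: int,
                   y: np.ndarray | None = None,
                   max_redraws: int = 1000) -> ResamplePlan:
    """With-replacement resamples of size n; out-of-bag indices recorded.

    If ``y`` is given, replicates whose in-bag labels collapse to a single
    class are redrawn (the count is recorded on the plan).
    """
    rng = _stream(seed, "boot")
    reps, oob, redrawn = [], [], 0
    while len(reps) < n_boot:
        idx = rng.integers(n, size=n)
        if y is not None and np.unique(np.asarray(y)[idx]).size < 2:
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("could not draw a two-class bootstrap replicate")
            continue
        reps.append(idx)
        oob.append(np.setdiff1d(np.arange(n), idx))
    indices = (np.stack(reps) if reps
               else np.empty((0, n), dtype=np.int64))
    return ResamplePlan(kind="bootstrap", n=n, seed=seed, indices=indices,
                        oob=oob, n_redrawn=redrawn)
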