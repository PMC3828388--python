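import matplotlib
import numpy as np
import pytest

import repromap as rm

matplotlib.use("Agg")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small separable trial dataset for fast classifier tests."""
    spec = rm.SyntheticSpec(n_trials=80, n_voxels=60, grid_shape=(5, 4, 3),
                            n_signal_voxels=10, n_signal_clusters=2,
                            effect_size=2.0, seed=3)
    return rm.make_trial_dataset(spec)


@pytest.fixture(scope="session")
def medium_run():
    """A moderate end-to-end grid run shared by several statistical tests.

    n=200 trials, p=500 voxels, 6x6 grid, 10-fold x 2 repeats (B=20).
    """
    spec = rm.SyntheticSpec(n_trials=200, n_voxels=500,
                            grid_shape=(10, 10, 5), n_signal_voxels=25,
                            n_signal_clusters=3, effect_size=1.0, seed=42)
    ds, truth = rm.make_trial_dataset(spec)
    grid = rm.default_grid(ds.X, ds.y, n_lambda1=6, n_lambda2=6)
    plan = rm.make_cv_plan(ds.n_trials, 10, 2, seed=42, y=ds.y)
    family = rm.fit_grid_family(ds.X, ds.y, grid, plan, max_voxels=400)
    summary = rm.summarize_grid(family)
    return {"ds": ds, "truth": truth, "grid": grid, "plan": plan,
            "family": family, "summary": summary}
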