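import numpy as np
import pytest

import mgfa
from mgfa.model import TrainingOptions


@pytest.fixture
def small_gaussian():
    """Small two-group, two-view gaussian dataset with truth, centered."""
    spec = mgfa.SimulationSpec(
        n_factors=3, n_samples=(40, 30), n_features=(25, 20),
        likelihoods=("gaussian", "gaussian"), noise_var=(1.0, 1.0),
        missing_fraction=0.15, seed=1,
    )
    ds, truth = mgfa.simulate(spec)
    return ds.center_per_group(), truth


@pytest.fixture
def mixed_likelihoods():
    """Small dataset mixing gaussian and bernoulli views, centered."""
    spec = mgfa.SimulationSpec(
        n_factors=2, n_samples=(30, 25), n_features=(15, 18),
        likelihoods=("gaussian", "bernoulli"), noise_var=(1.0, 0.0),
        missing_fraction=0.2, seed=3,
    )
    ds, truth = mgfa.simulate(spec)
    return ds.center_per_group(), truth


def quick_opts(**kw):
    kw.setdefault("n_factors", 3)
    kw.setdefault("max_iterations", 50)
    kw.setdefault("convergence_tol", 1e-7)
    kw.setdefault("tol_scale", "relative")
    return TrainingOptions(**kw)


@pytest.fixture
def fitted(small_gaussian):
    ds, truth = small_gaussian
    state, trace = mgfa.fit(ds, quick_opts())
    return ds, truth, state, trace
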