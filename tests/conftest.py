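import numpy as np
import pytest

import omifa
from omifa.state import TrainingConfig


@pytest.fixture(scope="session")
def tiny_gaussian():
    """Two gaussian views, N=8, D=(5,4), K_true=2, some missing entries."""
    ds, truth = omifa.simulate_dataset(
        n_views=2, n_samples=8, n_features=[5, 4], k_true=2,
        missing_fraction=0.15, seed=42,
    )
    return ds, truth


@pytest.fixture(scope="session")
def small_gaussian():
    ds, truth = omifa.simulate_dataset(
        n_views=2, n_samples=40, n_features=60, k_true=3, seed=7,
    )
    return ds, truth


@pytest.fixture(scope="session")
def small_trained(small_gaussian):
    ds, truth = small_gaussian
    cfg = TrainingConfig(K_initial=6, n_restarts=1, max_iterations=200)
    model = omifa.train_once(ds, cfg, seed=0)
    return model, ds, truth


@pytest.fixture(scope="session")
def mixed_dataset():
    ds, truth = omifa.simulate_dataset(
        n_views=3, n_samples=40, n_features=50, k_true=2,
        likelihoods=["gaussian", "bernoulli", "poisson"],
        missing_fraction=0.1, seed=11,
    )
    return ds, truth
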