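import numpy as np
import pytest

from rnapulse import FitConfig, ScaleFactors, SimConfig, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 25-gene noisy synthetic dataset with its generating truth."""
    cfg = SimConfig(n_genes=25, seed=5)
    expr, truth = make_dataset(cfg)
    return expr, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    cfg = SimConfig(n_genes=12, seed=9, noise_cv=0.0)
    expr, truth = make_dataset(cfg)
    return expr, truth


@pytest.fixture
def fast_fit_config():
    return FitConfig(n_restarts=5, seed=13)


@pytest.fixture
def true_sf():
    return ScaleFactors(c1=0.2, c2=0.8)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
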