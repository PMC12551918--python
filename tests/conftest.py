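import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ridgepen as rp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_correlated_dataset(rng, n=30, p=5, rho=0.7, sigma=1.0):
    """Equicorrelated design with a known linear signal."""
    S = rp.equicorrelated_sigma(p, rho)
    X = rng.standard_normal((n, p)) @ np.linalg.cholesky(S).T
    beta = rp.make_beta("equal", p)
    y = 2.0 + X @ beta + sigma * rng.standard_normal(n)
    return rp.Dataset(predictors=X, response=y)


@pytest.fixture
def toy_dataset(rng):
    return make_correlated_dataset(rng)


@pytest.fixture
def toy_pipeline(toy_dataset):
    design = rp.standardize(toy_dataset)
    canonical = rp.canonical_transform(design)
    return toy_dataset, design, canonical
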