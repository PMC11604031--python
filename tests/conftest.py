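import numpy as np
import pytest

from kldomain import GaussianGridParams, GridDomain


def random_pd_params(rng, p, grid=None, scale=1.0):
    """Random Gaussian grid parameters with a well-conditioned PD covariance."""
    if grid is None:
        grid = GridDomain.regular(0.0, 1.0, p)
    a = rng.normal(size=(p, p))
    cov = a @ a.T / p + scale * np.eye(p)
    mean = rng.normal(size=p)
    return GaussianGridParams(grid=grid, mean=mean, cov=cov)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_grid():
    return GridDomain.regular(0.0, 1.0, 5)
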