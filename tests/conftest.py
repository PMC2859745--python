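import numpy as np
import pytest
import scipy.sparse as sp

from dhglm import Scenario, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def oneway_data():
    """Balanced one-way heteroskedastic dataset at the default settings."""
    return simulate(Scenario(n_obs=2000, n_groups=100, seed=42))


@pytest.fixture(scope="session")
def homoskedastic_data():
    """LMM data with constant residual variance (no dispersion effects)."""
    return simulate(Scenario(n_obs=200, n_groups=20, sigma_u2=0.5,
                             sigma_d2=0.0, beta_d=(0.5, 0.0), seed=7))


def one_hot(groups, q):
    n = len(groups)
    return sp.csr_matrix((np.ones(n), (np.arange(n), groups)), shape=(n, q))
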