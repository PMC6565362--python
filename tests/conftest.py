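import numpy as np
import pytest
from hypothesis import settings

from multicue.netsim import NetworkParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_params() -> NetworkParams:
    """Coarse, fast network for unit tests (full-scale runs live in the
    acceptance tests)."""
    return NetworkParams(n=36, dt=0.05, seed=7)


@pytest.fixture(scope="session")
def default_params() -> NetworkParams:
    return NetworkParams(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
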