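import numpy as np
import pytest

from dwellkin import RateConstantSet, SimulationConfig, build_four_state_scheme


@pytest.fixture(scope="session")
def rates8() -> RateConstantSet:
    """Published point estimates for the 8-repeat array."""
    return RateConstantSet(k1=0.17, km1=0.13, k2=1.1, km2=0.66, k3=0.36, km3=0.222)


@pytest.fixture(scope="session")
def rates12() -> RateConstantSet:
    return RateConstantSet(k1=0.135, km1=1.26, k2=0.31, km2=0.130, k3=0.043, km3=0.0435)


@pytest.fixture(scope="session")
def rates16() -> RateConstantSet:
    return RateConstantSet(k1=0.26, km1=0.43, k2=0.39, km2=0.299, k3=0.074, km3=0.078)


@pytest.fixture(scope="session")
def scheme():
    return build_four_state_scheme()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rates(rng: np.random.Generator, low: float = 1e-2, high: float = 1e2):
    """Log-uniform random positive rate set."""
    vals = 10 ** rng.uniform(np.log10(low), np.log10(high), 6)
    return RateConstantSet(*vals)
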