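import numpy as np
import pytest

from cat2eq5d import CatResponse, simulate_cohort
from cat2eq5d.simulate import SimParams


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort, fixed seed, shared across tests."""
    return simulate_cohort(SimParams(), seed=20260929)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimParams(n_patients=40), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cat(rng) -> CatResponse:
    return CatResponse(*rng.integers(0, 6, size=8))
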