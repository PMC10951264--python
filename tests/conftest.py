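import numpy as np
import pytest
from hypothesis import settings

from ivqcocoso import datasets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sepsis_sources():
    return datasets.sepsis_sources()


@pytest.fixture(scope="session")
def sepsis_directions():
    return datasets.sepsis_directions()


@pytest.fixture(scope="session")
def supplier_sources():
    return datasets.supplier_sources()


@pytest.fixture
def rng():
    return np.random.default_rng(20240319)


def random_valid_values(rng, shape, q):
    """Valid-by-construction bound quadruples of the given leading shape."""
    mu_hi = rng.uniform(0.0, 1.0, shape)
    nu_hi = rng.uniform(0.0, (1.0 - mu_hi**q) ** (1.0 / q))
    mu_lo = rng.uniform(0.0, mu_hi)
    nu_lo = rng.uniform(0.0, nu_hi)
    return np.stack([mu_lo, mu_hi, nu_lo, nu_hi], axis=-1)
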