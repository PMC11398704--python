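import numpy as np
import pytest

from mktl import MKTLParams, rvs
from mktl.datasets import load_fixture

#: parameter grid used by the distribution-level property tests
PARAM_GRID = [
    MKTLParams(e, b) for e in (0.3, 0.9, 1.5, 4.0) for b in (0.3, 0.9, 1.5, 4.0)
]


@pytest.fixture(scope="session")
def burr50():
    return load_fixture("burr50").values


@pytest.fixture(scope="session")
def soil_a15():
    return load_fixture("soil_a15").values


@pytest.fixture(scope="session")
def soil_b15():
    return load_fixture("soil_b15").values


@pytest.fixture(scope="session")
def continuous_sample():
    """A moderately large tie-free sample from known parameters."""
    truth = MKTLParams(0.9, 1.4)
    return truth, rvs(2000, truth, seed=20240901)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
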