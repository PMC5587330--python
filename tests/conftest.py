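import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from migetsim import build_grid, default_panel, five_unit_circuit

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blood_panel():
    return default_panel("blood")


@pytest.fixture(scope="session")
def saline_panel():
    return default_panel("saline")


@pytest.fixture(scope="session")
def default_grid():
    return build_grid()


@pytest.fixture
def nominal_circuit():
    return five_unit_circuit()


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
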