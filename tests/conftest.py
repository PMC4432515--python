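import numpy as np
import pytest

from confsim import ConfoundingScenario, fit_unimodal


@pytest.fixture(scope="session")
def unimodal():
    """The default mechanical-ventilation-style population (fit once)."""
    return fit_unimodal()


@pytest.fixture(scope="session")
def low_scenario():
    return ConfoundingScenario.low()


@pytest.fixture(scope="session")
def high_scenario():
    return ConfoundingScenario.high()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
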