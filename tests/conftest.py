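import numpy as np
import pytest

from crossbridge import (
    AttachDetachParams,
    EnergyParams,
    Scenario,
    tabulate_rates,
)

FIBER_T = 277.15


@pytest.fixture(scope="session")
def p_ref():
    """Reference-temperature landscape (310.15 K)."""
    return EnergyParams()


@pytest.fixture(scope="session")
def p_fiber():
    """Fiber-condition landscape (4 degC)."""
    return EnergyParams(T=FIBER_T)


@pytest.fixture(scope="session")
def ap_default():
    return AttachDetachParams()


@pytest.fixture(scope="session")
def sl_table(p_fiber):
    """SL rate table at fiber temperature (cached across the session)."""
    return tabulate_rates(Scenario.SL, p_fiber)


@pytest.fixture(scope="session")
def tables_fiber(p_fiber):
    return {s: tabulate_rates(s, p_fiber) for s in Scenario}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
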