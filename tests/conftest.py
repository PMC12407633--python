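import numpy as np
import pytest

from mtpolarity import (
    DynamicsParams,
    MechanismConfig,
    default_params_for,
    long_domain,
    short_domain,
)

DT_MIN = 1.0 / 60.0


@pytest.fixture
def params():
    return DynamicsParams()


@pytest.fixture
def unlimited_params():
    return DynamicsParams(T_tot=np.inf)


@pytest.fixture
def short():
    return short_domain()


@pytest.fixture
def long():
    return long_domain()


@pytest.fixture
def short_params(short):
    return default_params_for(short)


@pytest.fixture
def long_params(long):
    return default_params_for(long)


@pytest.fixture
def mech_off():
    return MechanismConfig(feedback_on=False, checkpoint_on=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)
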