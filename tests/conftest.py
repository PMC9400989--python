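import numpy as np
import pytest

from ufdexsy.model_core import (CoilProfile, CpmgSpec, EncodingSpec,
                                InstrumentSpec, TwoSiteSample)
from ufdexsy.synthetic import Scenario


@pytest.fixture(scope="session")
def instrument():
    return InstrumentSpec()


@pytest.fixture(scope="session")
def flat_instrument():
    return InstrumentSpec(coil=CoilProfile.flat())


@pytest.fixture(scope="session")
def encoding_spec():
    return EncodingSpec()


@pytest.fixture(scope="session")
def cpmg_spec():
    return CpmgSpec()


@pytest.fixture(scope="session")
def yeast_sample():
    return TwoSiteSample.yeast_water()


@pytest.fixture(scope="session")
def scenario():
    """Reference study conditions: D = 1.4/3.6e-9 m^2/s, p_intra = 0.24,
    k = 14 1/s, mixing times 10/30/100 ms, SNR 280."""
    return Scenario.reference(seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
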