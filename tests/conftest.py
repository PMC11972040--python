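import numpy as np
import pytest

from bnctdose import (
    BORON_BPA,
    CO60_PHOTON,
    GBM_U87_CO60,
    IrradiationProtocol,
    NEUTRON_CO60_REF,
    U87_KINETICS,
    XRAY_PHOTON,
)


@pytest.fixture(scope="session")
def kinetics():
    return U87_KINETICS


@pytest.fixture(scope="session")
def co60():
    return CO60_PHOTON


@pytest.fixture(scope="session")
def xray():
    return XRAY_PHOTON


@pytest.fixture(scope="session")
def neutron():
    return NEUTRON_CO60_REF


@pytest.fixture(scope="session")
def boron():
    return BORON_BPA


@pytest.fixture(scope="session")
def gbm_set():
    return GBM_U87_CO60


@pytest.fixture(scope="session")
def ten_minutes():
    return IrradiationProtocol(duration=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
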