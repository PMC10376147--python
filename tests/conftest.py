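import numpy as np
import pytest

from strainchar import AuxiliaryConstants, preset, simulate
from strainchar.params import STRAIN_LIBRARY


@pytest.fixture(scope="session")
def aux():
    return AuxiliaryConstants()


@pytest.fixture(scope="session")
def wg10():
    return STRAIN_LIBRARY["WG(10)"]


@pytest.fixture(scope="session")
def wg20():
    return STRAIN_LIBRARY["WG(20)"]


@pytest.fixture(scope="session")
def wgp20():
    return STRAIN_LIBRARY["WGP(20)"]


@pytest.fixture(scope="session")
def mbr10():
    return preset("MBR", S0=10)


@pytest.fixture(scope="session")
def str20():
    return preset("STR")


@pytest.fixture(scope="session")
def wg20_str_traj(wg20, str20):
    """One WG 20 g/L stirred-tank ground-truth trajectory, shared read-only."""
    return simulate(wg20, None, str20)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
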