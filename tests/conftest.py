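import numpy as np
import pytest

from qcewater import QCEParameters, synthetic_cluster_set, toy_water_set
from qcewater.constants import ATM


@pytest.fixture(scope="session")
def synthetic18():
    """The canonical 18-cluster water-like fixture (monomer..decamer,
    chain isomers for n=3,4, ion pairs for n>=5)."""
    return synthetic_cluster_set(1, 10)


@pytest.fixture(scope="session")
def toy():
    return toy_water_set()


@pytest.fixture(scope="session")
def water_params():
    """Reference parameterization of the synthetic fixture: calibrated so
    the seed-1 isobar reproduces water's ambient density and boiling point."""
    return QCEParameters(450.0, 1.48)


@pytest.fixture(scope="session")
def atm():
    return ATM
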