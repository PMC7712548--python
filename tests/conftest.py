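import warnings

import pytest

from crownpore.core import Conditions, IonSpecies, PoreGeometry, PoreChargeSet


@pytest.fixture
def conditions():
    return Conditions()


@pytest.fixture
def potassium():
    return IonSpecies.potassium()


@pytest.fixture
def geometry():
    return PoreGeometry()


@pytest.fixture
def crown_charges():
    return PoreChargeSet.crown_ether(q_oxygen=-0.54)


@pytest.fixture(autouse=True)
def _quiet_generator_warnings():
    """The default generator design includes one sparsely counted point
    (0% strain, 0.1 V); silence its expected low-count warning in tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*translocations per replica.*")
        yield
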