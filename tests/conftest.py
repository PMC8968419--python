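import numpy as np
import pytest

from cortdbs.binding import BloodGeometry, default_binding_params, typical_geometry
from cortdbs.params import AgeGroup, PopulationParams


@pytest.fixture(scope="session")
def binding():
    """Binding parameters calibrated once against the published anchors."""
    return default_binding_params()


@pytest.fixture(scope="session")
def child_geom():
    return typical_geometry(AgeGroup.CHILDREN_INFANTS)


@pytest.fixture(scope="session")
def neonate_geom():
    return typical_geometry(AgeGroup.NEONATE)


@pytest.fixture
def pop():
    return PopulationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
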