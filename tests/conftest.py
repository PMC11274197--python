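import numpy as np
import pytest

from apexfree.geometry import (GeometryParams, build_aortic_spring,
                               build_ellipsoid_lv, build_pericardial_springs)
from apexfree.mechanics import WallModel


@pytest.fixture(scope="session")
def geometry():
    """Default truncated-ellipsoid LV geometry."""
    return build_ellipsoid_lv()


@pytest.fixture(scope="session")
def springs(geometry):
    return build_pericardial_springs(geometry)


@pytest.fixture(scope="session")
def wall_model(geometry, springs):
    """Default wall model with pericardial and aortic springs."""
    aortic = build_aortic_spring(geometry, 0.5)
    return WallModel(geometry, springs=springs, aortic_spring=aortic,
                     n_gauss=(3, 6, 8))


@pytest.fixture(scope="session")
def passive_state(wall_model):
    """Passive inflation to 8 mmHg (session-cached equilibrium)."""
    return wall_model.solve_equilibrium(8.0, t_act=1.0, t_scale=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
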