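import numpy as np
import pytest

from tassaw import materials as mat
from tassaw import substrate as sub
from tassaw.field import ChannelGeometry, make_tassaw_field


@pytest.fixture(scope="session")
def water():
    return mat.load_material("water")


@pytest.fixture(scope="session")
def water_consistent(water):
    """Water with compressibility exactly 1/(rho c^2) for closed-form oracles."""
    from dataclasses import replace
    return replace(water, compressibility=water.derived_compressibility())


@pytest.fixture(scope="session")
def polystyrene():
    return mat.load_material("polystyrene")


@pytest.fixture(scope="session")
def linbo3_crystal():
    return mat.load_linbo3_crystal()


@pytest.fixture(scope="session")
def linbo3_128yx(linbo3_crystal):
    return mat.rotate_tensors(linbo3_crystal,
                              mat.CrystalCut.rotated_y_cut(128.0))


@pytest.fixture(scope="session")
def saw_mode_128yx(linbo3_128yx):
    return sub.saw_velocity_free_surface(linbo3_128yx, (3300.0, 4100.0))


@pytest.fixture()
def channel_geometry():
    return ChannelGeometry(length=4e-3, width=1e-3, height=75e-6)


@pytest.fixture()
def standing_wave_1d(water_consistent):
    """1D fluid standing wave along x (tilt 90 deg => x_r = x), p_a = 1 MPa."""
    geom = ChannelGeometry(length=400e-6, width=400e-6, height=75e-6)
    return make_tassaw_field(1e6, 400e-6, 90.0, geom, water_consistent)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260904)
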