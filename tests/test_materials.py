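import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tassaw import materials as mat


# ---------------------------------------------------------------------------
# library records
# ---------------------------------------------------------------------------

def test_library_contains_expected_media():
    lib = mat.load_library()
    for name in ("water", "polystyrene", "pdms", "linbo3_128yx", "wbc", "mcf7"):
        assert name in lib


def test_fluid_compressibility_consistent_with_rho_c():
    water = mat.load_material("water")
    derived = mat.compressibility_from_rho_c(water.density, water.sound_speed)
    assert derived == pytest.approx(water.compressibility, rel=0.01)


def test_polystyrene_stored_kappa_matches_rho_c_not_landau():
    ps = mat.load_material("polystyrene")
    from_rho_c = mat.compressibility_from_rho_c(ps.density, ps.sound_speed)
    landau = mat.compressibility_landau(ps.poisson, ps.density, ps.sound_speed)
    assert from_rho_c == pytest.approx(ps.compressibility, rel=0.01)
    assert landau != pytest.approx(ps.compressibility, rel=0.05)


def test_consistency_report_warns_on_mismatch():
    rec = mat.MaterialRecord(name="odd", kind="fluid", density=1000.0,
                             sound_speed=1500.0, compressibility=9e-10)
    with pytest.warns(UserWarning, match="differs"):
        report = mat.consistency_report(rec)
    assert report["consistent"] is False


def test_invalid_record_rejected():
    with pytest.raises(mat.MaterialError):
        mat.MaterialRecord(name="bad", kind="fluid", density=-1.0)
    with pytest.raises(mat.MaterialError):
        mat.load_material("unobtainium")


# ---------------------------------------------------------------------------
# scalar derived quantities
# ---------------------------------------------------------------------------

def test_compressibility_from_rho_c_examples():
    # frozen from direct arithmetic: 1/(997*1497^2), 1/(1050*2350^2)
    assert mat.compressibility_from_rho_c(997, 1497) == pytest.approx(
        4.48e-10, rel=5e-3)
    assert mat.compressibility_from_rho_c(1050, 2350) == pytest.approx(
        1.72e-10, rel=5e-3)
    assert mat.compressibility_from_rho_c(1, 1) == 1.0
    with pytest.raises(mat.MaterialError):
        mat.compressibility_from_rho_c(-1, 1500)


def test_compressibility_landau():
    # sigma = 0.5 limit: prefactor is exactly 1
    assert mat.compressibility_landau(0.5, 1050, 2350) == pytest.approx(
        mat.compressibility_from_rho_c(1050, 2350), rel=1e-12)
    # direct arithmetic oracle: 3(1-0.35)/(1+0.35) / (1050*2350^2)
    direct = 3 * (1 - 0.35) / (1 + 0.35) / (1050 * 2350 ** 2)
    val = mat.compressibility_landau(0.35, 1050, 2350)
    assert val == pytest.approx(direct, rel=1e-12)
    # ... and it does NOT reproduce the tabulated 1.72e-10
    assert abs(val - 1.72e-10) / 1.72e-10 > 0.2
    with pytest.raises(mat.MaterialError):
        mat.compressibility_landau(-1.0, 1050, 2350)
    with pytest.raises(mat.MaterialError):
        mat.compressibility_landau(0.6, 1050, 2350)


def test_contrast_factor_examples():
    water = mat.load_material("water")
    ps = mat.load_material("polystyrene")
    phi = mat.contrast_factor(ps.density, ps.compressibility,
                              water.density, water.compressibility)
    # direct evaluation gives 0.667; see ledger for the 0.66-vs-0.67 rounding
    assert phi == pytest.approx(0.667, abs=5e-3)
    for cell in ("wbc", "mcf7"):
        rec = mat.load_material(cell)
        phic = mat.contrast_factor(rec.density, rec.compressibility,
                                   water.density, water.compressibility)
        assert round(phic, 2) == 0.13
    assert mat.contrast_factor(997, 4.48e-10, 997, 4.48e-10) == pytest.approx(
        0.0, abs=1e-14)


def test_contrast_factor_increasing_in_particle_density():
    rhos = np.linspace(500, 3000, 40)
    vals = [mat.contrast_factor(r, 2e-10, 997, 4.48e-10) for r in rhos]
    assert np.all(np.diff(vals) > 0)


def test_boundary_layer_thickness():
    water = mat.load_material("water")
    delta = mat.boundary_layer_thickness(water.dynamic_viscosity,
                                         water.density, 9.63e6)
    # direct arithmetic: sqrt(2*(0.89e-3/997)/(2 pi 9.63e6)) = 1.72e-7 m
    assert delta == pytest.approx(1.7178e-7, rel=1e-3)
    d4 = mat.boundary_layer_thickness(water.dynamic_viscosity,
                                      water.density, 4 * 9.63e6)
    assert d4 == pytest.approx(delta / 2.0, rel=1e-12)
    assert mat.boundary_layer_thickness(0.0, 997, 9.63e6) == 0.0


def test_voltage_to_dbm_examples():
    assert mat.voltage_to_dbm(10, 7.5, 26.5) == 29
    assert mat.voltage_to_dbm(5, 7.5, 26.5) == 23
    assert mat.voltage_to_dbm(7.5, 7.5, 26.5) == pytest.approx(26.5, abs=0.5)
    assert mat.voltage_to_dbm(7.5, 7.5, 26.5, rounding="none") == 26.5
    with pytest.raises(mat.MaterialError):
        mat.voltage_to_dbm(-1, 7.5, 26.5)


@given(v=st.floats(0.1, 100), a=st.floats(0.1, 50))
def test_voltage_to_dbm_depends_only_on_ratio(v, a):
    d1 = mat.voltage_to_dbm(a * v, 7.5, 26.5, rounding="none")
    d2 = mat.voltage_to_dbm(v, 7.5, 26.5, rounding="none")
    assert d1 - d2 == pytest.approx(20 * math.log10(a), abs=1e-9)


def test_frequency_from_wavelength():
    f = mat.frequency_from_wavelength(3997, 400e-6)
    assert 9e6 <= f <= 10e6
    assert f == pytest.approx(9.9925e6, rel=1e-6)
    assert mat.frequency_from_wavelength(3864, 200e-6) == pytest.approx(
        19.32e6, rel=1e-6)
    assert mat.frequency_from_wavelength(3997, 800e-6) == pytest.approx(
        f / 2, rel=1e-12)


# ---------------------------------------------------------------------------
# tensor rotation
# ---------------------------------------------------------------------------

def _rotate_full_tensors(tensors, a):
    """Independent oracle: rotate the full 4-/3-/2-index tensors directly."""
    c4 = np.einsum("ip,jq,kr,ls,pqrs->ijkl", a, a, a, a, tensors.stiffness_full)
    e3 = np.einsum("ip,jq,kr,pqr->ijk", a, a, a, tensors.piezo_full)
    eps = a @ tensors.permittivity @ a.T
    return c4, e3, eps


def test_rotate_identity_is_bitwise_noop(linbo3_crystal):
    rotated = mat.rotate_tensors(linbo3_crystal, mat.CrystalCut.identity())
    assert np.array_equal(rotated.stiffness, linbo3_crystal.stiffness)
    assert np.array_equal(rotated.piezo, linbo3_crystal.piezo)
    assert np.array_equal(rotated.permittivity, linbo3_crystal.permittivity)


@pytest.mark.parametrize("angle", [17.0, 38.0, 128.0, -61.5])
def test_rotation_then_inverse_recovers(linbo3_crystal, angle):
    cut = mat.CrystalCut.about_x(angle)
    back = mat.rotate_tensors(mat.rotate_tensors(linbo3_crystal, cut),
                              cut.inverse())
    assert np.allclose(back.stiffness, linbo3_crystal.stiffness, rtol=1e-10,
                       atol=1e-10 * np.abs(linbo3_crystal.stiffness).max())
    assert np.allclose(back.piezo, linbo3_crystal.piezo, rtol=1e-10,
                       atol=1e-10 * np.abs(linbo3_crystal.piezo).max())
    assert np.allclose(back.permittivity, linbo3_crystal.permittivity,
                       rtol=1e-10)


def test_permittivity_trace_invariant(linbo3_crystal, rng):
    for _ in range(5):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, 2 * math.pi)
        kmat = np.array([[0, -axis[2], axis[1]],
                         [axis[2], 0, -axis[0]],
                         [-axis[1], axis[0], 0]])
        a = (np.eye(3) + math.sin(angle) * kmat
             + (1 - math.cos(angle)) * kmat @ kmat)
        cut = mat.CrystalCut(a)
        rotated = mat.rotate_tensors(linbo3_crystal, cut)
        # direct 3x3 similarity-transform oracle
        direct = a @ linbo3_crystal.permittivity @ a.T
        assert np.allclose(rotated.permittivity, direct, rtol=1e-12)
        assert np.trace(rotated.permittivity) == pytest.approx(
            np.trace(linbo3_crystal.permittivity), rel=1e-12)


def test_bond_rotation_matches_full_tensor_oracle(linbo3_crystal):
    cut = mat.CrystalCut.rotated_y_cut(128.0)
    rotated = mat.rotate_tensors(linbo3_crystal, cut)
    c4, e3, eps = _rotate_full_tensors(linbo3_crystal, cut.rotation)
    assert np.allclose(rotated.stiffness_full, c4, rtol=1e-10,
                       atol=1e-6 * np.abs(c4).max())
    assert np.allclose(rotated.piezo_full, e3, rtol=1e-10,
                       atol=1e-10 * np.abs(e3).max())
    assert np.allclose(rotated.permittivity, eps, rtol=1e-12)


def test_full_360_rotation_is_identity(linbo3_crystal):
    out = linbo3_crystal
    for _ in range(8):
        out = mat.rotate_tensors(out, mat.CrystalCut.about_x(45.0))
    assert np.allclose(out.stiffness, linbo3_crystal.stiffness, rtol=1e-10,
                       atol=1e-10 * np.abs(linbo3_crystal.stiffness).max())
    assert np.allclose(out.piezo, linbo3_crystal.piezo, rtol=1e-10,
                       atol=1e-10 * np.abs(linbo3_crystal.piezo).max())


def test_bad_rotation_rejected_with_column_message():
    bad = np.eye(3)
    bad[0, 0] = 1.1
    with pytest.raises(mat.MaterialError, match="column 0"):
        mat.CrystalCut(bad)
    with pytest.raises(mat.MaterialError):
        mat.CrystalCut(-np.eye(3))  # improper (det = -1)


def test_rotated_tensor_set_keeps_invariants(linbo3_crystal):
    rotated = mat.rotate_tensors(linbo3_crystal,
                                 mat.CrystalCut.rotated_y_cut(128.0))
    assert np.allclose(rotated.stiffness, rotated.stiffness.T)
    assert np.all(np.linalg.eigvalsh(rotated.stiffness) > 0)
    assert np.all(np.linalg.eigvalsh(rotated.permittivity) > 0)
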