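import math

import numpy as np
import pytest

from tassaw import streaming as st
from tassaw.field import ChannelGeometry, make_tassaw_field

ETA = 0.89e-3


# ---------------------------------------------------------------------------
# interface velocities
# ---------------------------------------------------------------------------

def test_resting_wall_gives_fluid_velocity(standing_wave_1d):
    xs = np.linspace(0, 400e-6, 11)
    u, v, w = st.interface_velocities(standing_wave_1d, xs, np.zeros_like(xs))
    v1 = standing_wave_1d.velocity(xs, np.zeros_like(xs))
    assert np.allclose(u, v1[:, 0])
    assert np.allclose(v, v1[:, 1])
    assert np.allclose(w, 0.0)


def test_comoving_wall_gives_zero_tangentials(standing_wave_1d):
    xs = np.linspace(0, 400e-6, 11)
    v1 = standing_wave_1d.velocity(xs, np.zeros_like(xs))
    u, v, _ = st.interface_velocities(standing_wave_1d, xs, np.zeros_like(xs),
                                      wall_velocity=v1)
    assert np.allclose(u, 0.0) and np.allclose(v, 0.0)


def test_rotated_frame_agrees_with_global_projection(standing_wave_1d, rng):
    xs = np.linspace(0, 400e-6, 7)
    ang = 0.3
    frame = np.array([[math.cos(ang), math.sin(ang), 0.0],
                      [-math.sin(ang), math.cos(ang), 0.0],
                      [0.0, 0.0, 1.0]])
    u, v, w = st.interface_velocities(standing_wave_1d, xs, np.zeros_like(xs),
                                      frame=frame)
    v1 = standing_wave_1d.velocity(xs, np.zeros_like(xs))
    assert np.allclose(u, v1 @ frame[0])
    assert np.allclose(v, v1 @ frame[1])
    bad = np.array([[1.0, 0.2, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    with pytest.raises(st.StreamingError, match="orthonormal"):
        st.interface_velocities(standing_wave_1d, xs, np.zeros_like(xs),
                                frame=bad)


# ---------------------------------------------------------------------------
# limiting velocity
# ---------------------------------------------------------------------------

def test_classical_rayleigh_slip_analytic(standing_wave_1d):
    """u_L reduces to -(3/8)(v_a^2/c0) sin(2kx) for the 1D standing wave."""
    f = standing_wave_1d
    x = np.linspace(0, 400e-6, 201)
    y = np.array([0.0, 1e-6, 2e-6])
    slip = st.limiting_velocity_from_field(f, x, y)
    va = f.velocity_amplitude
    expected = -(3.0 / 8.0) * (va ** 2 / f.c0) * np.sin(2 * f.k_s * x)
    assert np.allclose(slip.u[1], expected,
                       atol=1e-12 * np.abs(expected).max())
    assert np.abs(slip.v).max() < 1e-15 * np.abs(slip.u).max()


def test_rayleigh_slip_central_differences_close_to_analytic(standing_wave_1d):
    """Independent numeric route: gridded amplitudes + central differences."""
    f = standing_wave_1d
    x = np.linspace(0, 400e-6, 801)
    y = np.array([0.0, 1e-6, 2e-6])
    xx, yy = np.meshgrid(x, y)
    u_a0, v_a0, w_a0 = st.interface_velocities(f, xx, yy)
    slip = st.limiting_velocity(u_a0, v_a0, w_a0, f.omega,
                                x[1] - x[0], y[1] - y[0])
    va = f.velocity_amplitude
    expected = -(3.0 / 8.0) * (va ** 2 / f.c0) * np.sin(2 * f.k_s * x)
    inner = slice(2, -2)
    assert np.allclose(slip.u[1, inner], expected[inner],
                       atol=2e-4 * np.abs(expected).max())


def test_zero_fields_give_zero_slip():
    z = np.zeros((3, 16), dtype=complex)
    slip = st.limiting_velocity(z, z, z, 2 * math.pi * 9.63e6, 1e-6, 1e-6)
    assert np.all(slip.u == 0.0) and np.all(slip.v == 0.0)
    assert np.isrealobj(slip.u) and np.isrealobj(slip.v)


def test_slip_magnitude_same_order_as_reported_maximum(standing_wave_1d):
    """(3/8) v_a^2/c0 at 1 MPa is ~0.11 mm/s, same order as 0.23 mm/s."""
    f = standing_wave_1d
    x = np.linspace(0, 400e-6, 401)
    slip = st.limiting_velocity_from_field(f, x, np.array([0.0, 1e-6]))
    peak = np.abs(slip.u).max()
    assert peak == pytest.approx(1.12e-4, rel=5e-3)
    assert 0.1 < peak / 0.23e-3 < 10.0


def test_slip_extrema_align_with_nodes_and_antinodes(water_consistent):
    geom = ChannelGeometry(2e-3, 1e-3, 75e-6)
    f = make_tassaw_field(1e6, 200e-6, 15.0, geom, water_consistent)
    y = np.linspace(0, geom.width, 4001)
    x = np.full_like(y, 1e-3)
    xx = np.vstack([x, x, x])
    yy = np.vstack([y, y, y])
    u_a0, v_a0, w_a0 = st.interface_velocities(f, xx, yy)
    jac = f.velocity_jacobian(xx, yy)
    slip = st.limiting_velocity(
        u_a0, v_a0, w_a0, f.omega, 1.0, y[1] - y[0],
        derivatives={"du_dx": jac[..., 0, 0], "du_dy": jac[..., 0, 1],
                     "dv_dx": jac[..., 1, 0], "dv_dy": jac[..., 1, 1]})
    mag = slip.magnitude()[1]
    # slip ~ |sin(2 k x_r)|: extrema (maxima) sit halfway between node and
    # antinode; zeros sit exactly on nodes and antinodes
    xr = f.x_r(x, y)
    phase = np.mod(f.k_s * xr, math.pi)
    zeros = y[np.nonzero((mag[1:-1] < mag[:-2]) & (mag[1:-1] < mag[2:]))[0] + 1]
    for yz in zeros:
        xrz = f.x_r(1e-3, yz)
        # distance to the nearest node/antinode locus (quarter-wavelength comb)
        d = abs((xrz % (f.wavelength / 4)))
        d = min(d, f.wavelength / 4 - d)
        assert d < 2e-7


# ---------------------------------------------------------------------------
# Stokes solver
# ---------------------------------------------------------------------------

def test_zero_slip_gives_rest(water_consistent):
    sof = st.solve_stokes(12, 4, 6, (4e-4, 2e-4, 1e-4), None, None, eta=ETA)
    assert np.all(sof.u == 0.0) and np.all(sof.w == 0.0)
    assert np.ptp(sof.p) == pytest.approx(0.0, abs=1e-20)


def _rayleigh_cell_oracle(s, h, amp, z):
    """Closed-form slip-driven streaming between plates (biharmonic psi)."""
    def basis(zz):
        return np.array([np.cosh(s * zz), np.sinh(s * zz),
                         zz * np.cosh(s * zz), zz * np.sinh(s * zz)])

    def dbasis(zz):
        return np.array([s * np.sinh(s * zz), s * np.cosh(s * zz),
                         np.cosh(s * zz) + s * zz * np.sinh(s * zz),
                         np.sinh(s * zz) + s * zz * np.cosh(s * zz)])

    m = np.vstack([basis(0.0), dbasis(0.0), basis(h), dbasis(h)])
    coeff = np.linalg.solve(m, np.array([0.0, amp, 0.0, 0.0]))
    return np.array([coeff @ dbasis(zz) for zz in z])


def test_2d_rolls_match_parallel_plate_solution():
    nx, nz = 192, 32
    lx, h = 400e-6, 75e-6
    s = 2 * 2 * math.pi / lx
    amp = 1e-4
    sof = st.solve_stokes(nx, 1, nz, (lx, 10e-6, h),
                          lambda xx, yy: amp * np.sin(s * xx), eta=ETA)
    dx, dz = lx / nx, h / nz
    xu = np.arange(nx) * dx
    zu = (np.arange(nz) + 0.5) * dz
    dphi = _rayleigh_cell_oracle(s, h, amp, zu)
    oracle = np.sin(s * xu)[:, None] * dphi[None, :]
    mid = nz // 2
    err = (np.abs(sof.u[:, 0, mid] - oracle[:, mid]).max()
           / np.abs(oracle[:, mid]).max())
    assert err < 0.05
    assert sof.max_divergence_rel() < 1e-8


def test_solution_linear_in_slip_amplitude():
    s = 2 * 2 * math.pi / 4e-4
    kw = dict(eta=ETA)
    a = st.solve_stokes(48, 1, 12, (4e-4, 1e-5, 7.5e-5),
                        lambda xx, yy: 1e-4 * np.sin(s * xx), **kw)
    b = st.solve_stokes(48, 1, 12, (4e-4, 1e-5, 7.5e-5),
                        lambda xx, yy: 2e-4 * np.sin(s * xx), **kw)
    assert np.allclose(b.u, 2 * a.u, rtol=1e-10,
                       atol=1e-10 * np.abs(a.u).max())
    assert np.allclose(b.w, 2 * a.w, rtol=1e-10,
                       atol=1e-10 * np.abs(a.w).max())


def test_gauge_independence_of_velocities():
    s = 2 * 2 * math.pi / 4e-4

    def slip_u(xx, yy):
        return 1e-4 * np.sin(s * xx) * np.sin(math.pi * yy / 2e-4)

    def slip_v(xx, yy):
        return 3e-5 * np.cos(s * xx) * np.sin(math.pi * yy / 2e-4)

    a = st.solve_stokes(24, 12, 6, (4e-4, 2e-4, 7.5e-5), slip_u, slip_v,
                        eta=ETA, pin_cell=0)
    b = st.solve_stokes(24, 12, 6, (4e-4, 2e-4, 7.5e-5), slip_u, slip_v,
                        eta=ETA, pin_cell=777)
    assert np.allclose(a.u, b.u, atol=1e-9 * np.abs(a.u).max())
    assert np.allclose(a.v, b.v, atol=1e-9 * np.abs(a.u).max())
    pa = a.p - a.p.mean()
    pb = b.p - b.p.mean()
    assert np.allclose(pa, pb, atol=1e-8 * max(np.abs(pa).max(), 1e-30))


def test_3d_divergence_below_tolerance():
    s = 2 * 2 * math.pi / 4e-4
    sof = st.solve_stokes(24, 12, 8, (4e-4, 2e-4, 7.5e-5),
                          lambda xx, yy: 1e-4 * np.sin(s * xx),
                          lambda xx, yy: 2e-5 * np.cos(s * xx), eta=ETA)
    assert sof.max_divergence_rel() < 1e-8


def test_grid_convergence_first_order_or_better():
    lx, h = 4e-4, 7.5e-5
    s = 2 * 2 * math.pi / lx
    amp = 1e-4

    def mid_velocity(nx, nz):
        sof = st.solve_stokes(nx, 1, nz, (lx, 1e-5, h),
                              lambda xx, yy: amp * np.sin(s * xx), eta=ETA)
        zu = (np.arange(nz) + 0.5) * (h / nz)
        dphi = _rayleigh_cell_oracle(s, h, amp, zu)
        oracle = np.sin(s * np.arange(nx) * (lx / nx))[:, None] * dphi[None, :]
        return np.abs(sof.u[:, 0, :] - oracle).max()

    e1 = mid_velocity(48, 8)
    e2 = mid_velocity(96, 16)
    e3 = mid_velocity(192, 32)
    order_a = math.log2(e1 / e2)
    order_b = math.log2(e2 / e3)
    assert order_a > 0.9 and order_b > 0.9  # observed ~2nd order


# ---------------------------------------------------------------------------
# validity diagnostics
# ---------------------------------------------------------------------------

def test_validity_at_device_conditions():
    rep = st.limiting_validity(2 * math.pi * 9.63e6, ETA, 997.0,
                               {"height": 75e-6})
    assert rep["valid"]
    assert rep["delta_nu"] == pytest.approx(1.72e-7, rel=5e-3)
    assert rep["delta_nu"] < 0.01 * 75e-6


def test_low_frequency_flagged_invalid():
    rep = st.limiting_validity(0.0, ETA, 997.0, {"height": 75e-6})
    assert not rep["valid"]
    rep2 = st.limiting_validity(1.0, ETA, 997.0, {"height": 75e-6})
    assert not rep2["valid"]


def test_small_curvature_radius_flagged():
    rep = st.limiting_validity(2 * math.pi * 9.63e6, ETA, 997.0,
                               {"height": 75e-6, "curvature_radius": 5e-7})
    assert not rep["valid"]
    assert any("curvature" in f for f in rep["flags"])
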