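"""Limiting-velocity slip condition and the second-order Stokes flow it drives.

The steady streaming just outside the viscous boundary layer on the vibrating
bottom wall is imposed as a tangential slip velocity (the *limiting
velocity*), computed from the complex first-order interface velocity
amplitudes ``(u_a0, v_a0, w_a0)``:

    u_L = -1/(4 w) Re{ u du*/dx + v du*/dy
                       + u* [ (2+i)(du/dx + dv/dy + dw/dz) - (2+3i) dw/dz ] }

and symmetrically for ``v_L``.  The bulk streaming obeys creeping (Stokes)
flow, solved on a staggered MAC grid with the slip on the bottom face,
no-slip on top/side walls, and periodic (default) or free ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tassaw.field import FirstOrderField
from tassaw.materials import boundary_layer_thickness


class StreamingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Interface velocities and the limiting-velocity formula
# ---------------------------------------------------------------------------

def interface_velocities(field1: FirstOrderField, x, y, z: float = 0.0,
                         wall_velocity=None, frame: Optional[np.ndarray] = None):
    """Complex interface velocity amplitudes (u_a0, v_a0, w_a0).

    Tangential components are fluid-minus-wall differences; the normal
    component is the (continuous) normal velocity.  ``wall_velocity`` is a
    complex (..., 3) array in the same frame, or None for a resting wall.
    ``frame`` is a 3x3 matrix whose rows are the interface x, y tangents and
    z normal expressed in global coordinates (default: global axes).
    """
    if frame is None:
        frame = np.eye(3)
    else:
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (3, 3) or not np.allclose(
                frame @ frame.T, np.eye(3), atol=1e-10):
            raise StreamingError("interface frame axes must be orthonormal")
    v1 = field1.velocity(x, y, z)
    v1 = v1 @ frame.T  # project onto interface axes
    if wall_velocity is None:
        wall = np.zeros_like(v1)
    else:
        wall = np.asarray(wall_velocity, dtype=complex) @ frame.T
    u_a0 = v1[..., 0] - wall[..., 0]
    v_a0 = v1[..., 1] - wall[..., 1]
    w_a0 = v1[..., 2]
    return u_a0, v_a0, w_a0


@dataclass
class LimitingVelocityField:
    """Tangential slip (u_L, v_L) on a planar interface grid."""

    x: np.ndarray            # (nx,)
    y: np.ndarray            # (ny,)
    u: np.ndarray            # (ny, nx), m/s
    v: np.ndarray            # (ny, nx), m/s
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: np.ndarray = field(default_factory=lambda: np.eye(3))

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def probe_line(self, axis: str = "x", index: Optional[int] = None):
        """|slip| along a grid line (mirrors a center-line magnitude plot)."""
        mag = self.magnitude()
        if axis == "x":
            i = mag.shape[0] // 2 if index is None else index
            return self.x, mag[i, :]
        i = mag.shape[1] // 2 if index is None else index
        return self.y, mag[:, i]


def _grad2d(arr: np.ndarray, dx: float, dy: float):
    """(d/dx, d/dy) central differences; size-1 axes get zero derivative."""
    ddx = np.zeros_like(arr)
    ddy = np.zeros_like(arr)
    if arr.shape[1] > 1:
        ddx = np.gradient(arr, dx, axis=1)
    if arr.shape[0] > 1:
        ddy = np.gradient(arr, dy, axis=0)
    return ddx, ddy


def limiting_velocity(u_a0: np.ndarray, v_a0: np.ndarray, w_a0: np.ndarray,
                      omega: float, dx: float, dy: float,
                      dw_dz: Optional[np.ndarray] = None,
                      derivatives: Optional[dict] = None,
                      x: Optional[np.ndarray] = None,
                      y: Optional[np.ndarray] = None) -> LimitingVelocityField:
    """Evaluate the limiting-velocity expression on an interface grid.

    Arrays are (ny, nx) complex amplitudes in the interface frame.  Spatial
    derivatives default to 2nd-order central differences; pass ``derivatives``
    (keys ``du_dx, du_dy, dv_dx, dv_dy``) for analytic values.  ``dw_dz`` is
    the normal derivative of the normal component at the wall (zero for a
    z-uniform first-order field).
    """
    if omega <= 0:
        raise StreamingError("omega must be positive")
    u_a0 = np.asarray(u_a0, dtype=complex)
    v_a0 = np.asarray(v_a0, dtype=complex)
    w_a0 = np.asarray(w_a0, dtype=complex)
    if dw_dz is None:
        dw_dz = np.zeros_like(u_a0)
    if derivatives is None:
        du_dx, du_dy = _grad2d(u_a0, dx, dy)
        dv_dx, dv_dy = _grad2d(v_a0, dx, dy)
    else:
        du_dx = derivatives["du_dx"]
        du_dy = derivatives["du_dy"]
        dv_dx = derivatives["dv_dx"]
        dv_dy = derivatives["dv_dy"]

    div_t = du_dx + dv_dy + dw_dz
    c1 = 2.0 + 1.0j
    c2 = 2.0 + 3.0j
    u_l = -1.0 / (4.0 * omega) * np.real(
        u_a0 * np.conj(du_dx) + v_a0 * np.conj(du_dy)
        + np.conj(u_a0) * (c1 * div_t - c2 * dw_dz))
    v_l = -1.0 / (4.0 * omega) * np.real(
        u_a0 * np.conj(dv_dx) + v_a0 * np.conj(dv_dy)
        + np.conj(v_a0) * (c1 * div_t - c2 * dw_dz))
    nx = u_a0.shape[1]
    ny = u_a0.shape[0]
    xv = np.arange(nx) * dx if x is None else np.asarray(x, dtype=float)
    yv = np.arange(ny) * dy if y is None else np.asarray(y, dtype=float)
    return LimitingVelocityField(x=xv, y=yv, u=u_l, v=v_l)


def limiting_velocity_from_field(field1: FirstOrderField, x: np.ndarray,
                                 y: np.ndarray, z: float = 0.0,
                                 wall_velocity=None) -> LimitingVelocityField:
    """Analytic-derivative limiting velocity of a built-in field on a grid.

    For the built-in z-uniform field the wall-normal fluid velocity vanishes,
    so ``w_a0 = 0`` and ``dw/dz = 0``; tangential derivatives come from the
    field's analytic Jacobian.
    """
    xx, yy = np.meshgrid(np.asarray(x, float), np.asarray(y, float))
    u_a0, v_a0, w_a0 = interface_velocities(field1, xx, yy, z, wall_velocity)
    jac = field1.velocity_jacobian(xx, yy, z)
    derivs = {
        "du_dx": jac[..., 0, 0], "du_dy": jac[..., 0, 1],
        "dv_dx": jac[..., 1, 0], "dv_dy": jac[..., 1, 1],
    }
    dx = x[1] - x[0] if len(np.atleast_1d(x)) > 1 else 1.0
    dy = y[1] - y[0] if len(np.atleast_1d(y)) > 1 else 1.0
    out = limiting_velocity(u_a0, v_a0, w_a0, field1.omega, dx, dy,
                            dw_dz=jac[..., 2, 2], derivatives=derivs)
    out.x = np.asarray(x, float)
    out.y = np.asarray(y, float)
    return out


# ---------------------------------------------------------------------------
# Second-order (streaming) Stokes solve on a staggered MAC grid
# ---------------------------------------------------------------------------

@dataclass
class SecondOrderField:
    """Steady streaming velocity/pressure on a staggered channel grid.

    ``u`` lives on x-faces (nx, ny, nz), ``v`` on interior y-faces
    (nx, ny-1, nz), ``w`` on interior z-faces (nx, ny, nz-1), ``p`` at cell
    centers (nx, ny, nz).  x is periodic; boundary-normal velocities vanish.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    lengths: tuple[float, float, float]
    eta: float

    @property
    def shape(self):
        return self.p.shape

    @property
    def spacing(self):
        nx, ny, nz = self.p.shape
        lx, ly, lz = self.lengths
        return lx / nx, ly / ny, lz / nz

    def cell_centers(self):
        nx, ny, nz = self.p.shape
        dx, dy, dz = self.spacing
        return ((np.arange(nx) + 0.5) * dx, (np.arange(ny) + 0.5) * dy,
                (np.arange(nz) + 0.5) * dz)

    def divergence(self) -> np.ndarray:
        """Discrete cell divergence (zero boundary-normal fluxes)."""
        nx, ny, nz = self.p.shape
        dx, dy, dz = self.spacing
        du = (np.roll(self.u, -1, axis=0) - self.u) / dx
        vfull = np.zeros((nx, ny + 1, nz))
        vfull[:, 1:ny, :] = self.v
        dv = (vfull[:, 1:, :] - vfull[:, :-1, :]) / dy
        wfull = np.zeros((nx, ny, nz + 1))
        wfull[:, :, 1:nz] = self.w
        dw = (wfull[:, :, 1:] - wfull[:, :, :-1]) / dz
        return du + dv + dw

    def max_divergence_rel(self) -> float:
        flux = max(np.max(np.abs(self.u)), np.max(np.abs(self.v), initial=0.0),
                   np.max(np.abs(self.w), initial=0.0), 1e-300)
        dmin = min(self.spacing)
        return float(np.max(np.abs(self.divergence())) * dmin / flux)

    def velocity_at_centers(self) -> np.ndarray:
        """Cell-centered velocity by face averaging, shape (nx, ny, nz, 3)."""
        nx, ny, nz = self.p.shape
        uc = 0.5 * (self.u + np.roll(self.u, -1, axis=0))
        vfull = np.zeros((nx, ny + 1, nz))
        vfull[:, 1:ny, :] = self.v
        vc = 0.5 * (vfull[:, :-1, :] + vfull[:, 1:, :])
        wfull = np.zeros((nx, ny, nz + 1))
        wfull[:, :, 1:nz] = self.w
        wc = 0.5 * (wfull[:, :, :-1] + wfull[:, :, 1:])
        return np.stack([uc, vc, wc], axis=-1)


def _idx(nx, ny, nz):
    return np.arange(nx * ny * nz).reshape(nx, ny, nz)


def solve_stokes(nx: int, ny: int, nz: int,
                 lengths: tuple[float, float, float],
                 slip_u, slip_v=None, eta: float = 1e-3,
                 end_condition: str = "periodic",
                 pin_cell: int = 0) -> SecondOrderField:
    """Solve creeping flow driven by tangential slip on the bottom face.

    Boundary conditions: slip (u, v) = (slip_u, slip_v) at z=0, no-slip top
    and side walls, periodic in x (``end_condition='periodic'``, the default
    and currently only option).  ``slip_u``/``slip_v`` are callables of (x, y)
    or arrays broadcastable to the bottom-face grids.  The singular pressure
    nullspace is removed by pinning cell ``pin_cell`` to zero pressure.

    Solution is exactly linear in the slip amplitude; the discrete divergence
    of the result is checked against 1e-8 (relative to the peak face flux).
    """
    if end_condition != "periodic":
        raise StreamingError(
            f"end_condition {end_condition!r} not supported (use 'periodic')")
    if nz < 2:
        raise StreamingError("need at least 2 cells across the channel height")
    lx, ly, lz = lengths
    dx, dy, dz = lx / nx, ly / ny, lz / nz
    two_d = ny == 1

    def face_values(fun, xs, ys):
        if callable(fun):
            xx, yy = np.meshgrid(xs, ys, indexing="ij")
            return np.asarray(fun(xx, yy), dtype=float)
        if fun is None:
            return np.zeros((len(xs), len(ys)))
        return np.broadcast_to(np.asarray(fun, dtype=float),
                               (len(xs), len(ys))).copy()

    xs_u = np.arange(nx) * dx                # u-face x-positions
    ys_u = (np.arange(ny) + 0.5) * dy
    xs_v = (np.arange(nx) + 0.5) * dx
    ys_v = np.arange(1, ny) * dy             # interior y-faces
    slip_u_b = face_values(slip_u, xs_u, ys_u)          # (nx, ny)
    slip_v_b = face_values(slip_v, xs_v, ys_v) if not two_d else None

    iu = _idx(nx, ny, nz)
    nu = iu.size
    off = nu
    if two_d:
        iv = None
        nv = 0
    else:
        iv = off + _idx(nx, ny - 1, nz)
        nv = iv.size
        off += nv
    iw = off + _idx(nx, ny, nz - 1)
    nw = iw.size
    off += nw
    ip = off + _idx(nx, ny, nz)
    ntot = off + ip.size

    rows, cols, vals = [], [], []
    rhs = np.zeros(ntot)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    inv_dx2, inv_dy2, inv_dz2 = 1.0 / dx ** 2, 1.0 / dy ** 2, 1.0 / dz ** 2

    # ---- u-momentum: eta lap(u) - dp/dx = 0 at u-face (i-1/2, j, k)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                r = iu[i, j, k]
                diag = 0.0
                # x-neighbors (periodic)
                add(r, iu[(i + 1) % nx, j, k], inv_dx2)
                add(r, iu[(i - 1) % nx, j, k], inv_dx2)
                diag -= 2.0 * inv_dx2
                # y-neighbors (walls: ghost no-slip)
                if not two_d:
                    if j + 1 < ny:
                        add(r, iu[i, j + 1, k], inv_dy2)
                        diag -= inv_dy2
                    else:
                        diag -= 2.0 * inv_dy2  # wall ghost: -u
                    if j - 1 >= 0:
                        add(r, iu[i, j - 1, k], inv_dy2)
                        diag -= inv_dy2
                    else:
                        diag -= 2.0 * inv_dy2
                # z-neighbors: bottom slip ghost, top no-slip ghost
                if k + 1 < nz:
                    add(r, iu[i, j, k + 1], inv_dz2)
                    diag -= inv_dz2
                else:
                    diag -= 2.0 * inv_dz2  # top no-slip ghost
                if k - 1 >= 0:
                    add(r, iu[i, j, k - 1], inv_dz2)
                    diag -= inv_dz2
                else:
                    diag -= 2.0 * inv_dz2  # bottom slip ghost
                    rhs[r] -= 2.0 * inv_dz2 * slip_u_b[i, j]
                add(r, r, diag)
                # -dp/dx / eta : (p[i] - p[i-1]) / dx
                add(r, ip[i, j, k], -1.0 / (eta * dx))
                add(r, ip[(i - 1) % nx, j, k], 1.0 / (eta * dx))

    # ---- v-momentum at interior y-faces (i, j-1/2, k), j = 1..ny-1
    if not two_d:
        for i in range(nx):
            for j in range(1, ny):
                for k in range(nz):
                    r = iv[i, j - 1, k]
                    diag = 0.0
                    add(r, iv[(i + 1) % nx, j - 1, k], inv_dx2)
                    add(r, iv[(i - 1) % nx, j - 1, k], inv_dx2)
                    diag -= 2.0 * inv_dx2
                    # y-neighbor faces (wall faces carry v=0 exactly)
                    if j + 1 <= ny - 1:
                        add(r, iv[i, j, k], inv_dy2)
                    diag -= 2.0 * inv_dy2
                    if j - 1 >= 1:
                        add(r, iv[i, j - 2, k], inv_dy2)
                    # z-neighbors: bottom slip ghost, top no-slip ghost
                    if k + 1 < nz:
                        add(r, iv[i, j - 1, k + 1], inv_dz2)
                        diag -= inv_dz2
                    else:
                        diag -= 2.0 * inv_dz2  # top no-slip ghost
                    if k - 1 >= 0:
                        add(r, iv[i, j - 1, k - 1], inv_dz2)
                        diag -= inv_dz2
                    else:
                        diag -= 2.0 * inv_dz2  # bottom slip ghost
                        rhs[r] -= 2.0 * inv_dz2 * slip_v_b[i, j - 1]
                    add(r, r, diag)
                    add(r, ip[i, j, k], -1.0 / (eta * dy))
                    add(r, ip[i, j - 1, k], 1.0 / (eta * dy))

    # ---- w-momentum at interior z-faces (i, j, k-1/2), k = 1..nz-1
    for i in range(nx):
        for j in range(ny):
            for k in range(1, nz):
                r = iw[i, j, k - 1]
                diag = 0.0
                add(r, iw[(i + 1) % nx, j, k - 1], inv_dx2)
                add(r, iw[(i - 1) % nx, j, k - 1], inv_dx2)
                diag -= 2.0 * inv_dx2
                if not two_d:
                    if j + 1 < ny:
                        add(r, iw[i, j + 1, k - 1], inv_dy2)
                        diag -= inv_dy2
                    else:
                        diag -= 2.0 * inv_dy2  # wall ghost: -w
                    if j - 1 >= 0:
                        add(r, iw[i, j - 1, k - 1], inv_dy2)
                        diag -= inv_dy2
                    else:
                        diag -= 2.0 * inv_dy2
                # z-neighbor faces (boundary faces carry w=0 exactly)
                if k + 1 <= nz - 1:
                    add(r, iw[i, j, k], inv_dz2)
                diag -= 2.0 * inv_dz2
                if k - 1 >= 1:
                    add(r, iw[i, j, k - 2], inv_dz2)
                add(r, r, diag)
                add(r, ip[i, j, k], -1.0 / (eta * dz))
                add(r, ip[i, j, k - 1], 1.0 / (eta * dz))

    # ---- continuity per cell (pin one pressure to fix the gauge)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                r = ip[i, j, k]
                if r - ip.flat[0] == pin_cell:
                    add(r, r, 1.0)
                    continue
                add(r, iu[(i + 1) % nx, j, k], 1.0 / dx)
                add(r, iu[i, j, k], -1.0 / dx)
                if not two_d:
                    if j + 1 <= ny - 1:
                        add(r, iv[i, j, k], 1.0 / dy)
                    if j >= 1:
                        add(r, iv[i, j - 1, k], -1.0 / dy)
                if k + 1 <= nz - 1:
                    add(r, iw[i, j, k], 1.0 / dz)
                if k >= 1:
                    add(r, iw[i, j, k - 1], -1.0 / dz)

    mat = sp.csc_matrix((vals, (rows, cols)), shape=(ntot, ntot))
    sol = spla.spsolve(mat, rhs)
    if not np.all(np.isfinite(sol)):
        raise StreamingError("Stokes linear solve did not converge (non-finite)")
    resid = np.linalg.norm(mat @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8:
        raise StreamingError(f"Stokes linear solve residual {resid:.2e} > 1e-8")

    u = sol[:nu].reshape(nx, ny, nz)
    v = (sol[nu:nu + nv].reshape(nx, ny - 1, nz) if not two_d
         else np.zeros((nx, 0, nz)))
    w = sol[nu + nv:nu + nv + nw].reshape(nx, ny, nz - 1)
    p = eta * sol[nu + nv + nw:].reshape(nx, ny, nz)
    out = SecondOrderField(u=u, v=v, w=w, p=p, lengths=(lx, ly, lz), eta=eta)
    if out.max_divergence_rel() > 1e-8:
        raise StreamingError(
            f"discrete divergence {out.max_divergence_rel():.2e} exceeds 1e-8")
    return out


def solve_stokes_from_slip(slip: LimitingVelocityField, height: float,
                           nx: int, ny: int, nz: int,
                           eta: float) -> SecondOrderField:
    """Solve the channel streaming flow driven by a LimitingVelocityField."""
    lx = slip.x[-1] - slip.x[0] + (slip.x[1] - slip.x[0])
    ly = slip.y[-1] - slip.y[0] + (slip.y[1] - slip.y[0])
    from scipy.interpolate import RegularGridInterpolator
    ui = RegularGridInterpolator((slip.y, slip.x), slip.u, bounds_error=False,
                                 fill_value=None)
    vi = RegularGridInterpolator((slip.y, slip.x), slip.v, bounds_error=False,
                                 fill_value=None)
    x0, y0 = slip.x[0], slip.y[0]

    def su(xx, yy):
        return ui(np.stack([yy + y0, xx + x0], axis=-1))

    def sv(xx, yy):
        return vi(np.stack([yy + y0, xx + x0], axis=-1))

    return solve_stokes(nx, ny, nz, (lx, ly, height), su, sv, eta=eta)


# ---------------------------------------------------------------------------
# Validity diagnostics
# ---------------------------------------------------------------------------

def limiting_validity(omega: float, eta: float, rho: float,
                      length_scales: dict) -> dict:
    """Check the slip-condition assumptions for the given regime.

    ``length_scales`` may contain ``height`` (channel height) and
    ``curvature_radius`` (smallest boundary curvature radius); the method
    requires a thin boundary layer (delta << height, delta << curvature) and
    a large Womersley-type number |M| = L sqrt(omega rho / eta) >> 1.
    """
    report = {"omega": omega, "valid": True, "flags": []}
    if omega <= 0:
        report["valid"] = False
        report["flags"].append("omega must be positive (|M| >> 1 violated)")
        report["delta_nu"] = math.inf
        return report
    freq = omega / (2.0 * math.pi)
    delta = boundary_layer_thickness(eta, rho, freq)
    report["delta_nu"] = delta
    height = length_scales.get("height")
    if height is not None:
        m = height * math.sqrt(omega * rho / eta)
        report["womersley"] = m
        report["delta_over_height"] = delta / height
        if m < 10.0:
            report["valid"] = False
            report["flags"].append(f"|M| = {m:.2f} not >> 1")
        if delta > 0.1 * height:
            report["valid"] = False
            report["flags"].append("boundary layer not thin vs channel height")
    radius = length_scales.get("curvature_radius")
    if radius is not None and delta > 0.1 * radius:
        report["valid"] = False
        report["flags"].append(
            "boundary curvature radius comparable to boundary layer")
    return report
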