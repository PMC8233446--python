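"""Free-surface SAW solver on a rotated piezoelectric half-space.

Partial-wave (Stroh-type) formalism with the quasi-static electric
approximation: plane waves ``exp(i k (x + alpha z - v t))`` in the half-space
``z <= 0`` (z is the outward surface normal), four coupled degrees of freedom
(three displacements plus the electric potential).  The surface boundary
conditions are traction-free and charge-free (``D_z = 0``) by default; a
shorted surface (``phi = 0``) is available as an option.

Leaky/pseudo-SAW branches (complex velocity roots) are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import linalg, optimize

from tassaw.materials import PiezoTensorSet

_DECAY_IM_TOL = 1e-9


class SawSolverError(RuntimeError):
    """Eigensystem or root-finding failure in the SAW solver."""


# ---------------------------------------------------------------------------
# Partial-wave eigenproblem
# ---------------------------------------------------------------------------

def _quadratic_blocks(tensors: PiezoTensorSet, v: float):
    """Matrices A0 + alpha A1 + alpha^2 A2 of the 4x4 quasi-static problem."""
    c = tensors.stiffness_full
    e = tensors.piezo_full
    eps = tensors.permittivity
    rho = tensors.density

    a0 = np.zeros((4, 4))
    a1 = np.zeros((4, 4))
    a2 = np.zeros((4, 4))
    a0[:3, :3] = c[:, 0, :, 0] - rho * v * v * np.eye(3)
    a1[:3, :3] = c[:, 0, :, 2] + c[:, 2, :, 0]
    a2[:3, :3] = c[:, 2, :, 2]
    a0[:3, 3] = e[0, :, 0]
    a1[:3, 3] = e[0, :, 2] + e[2, :, 0]
    a2[:3, 3] = e[2, :, 2]
    a0[3, :3] = a0[:3, 3]
    a1[3, :3] = a1[:3, 3]
    a2[3, :3] = a2[:3, 3]
    a0[3, 3] = -eps[0, 0]
    a1[3, 3] = -(eps[0, 2] + eps[2, 0])
    a2[3, 3] = -eps[2, 2]

    # Balance the ~1e22 scale gap between stiffness and permittivity entries
    # by symmetrically rescaling the potential degree of freedom; the returned
    # eigenvectors must be unscaled with the same factor.
    scale = math.sqrt(np.linalg.norm(c) / np.linalg.norm(eps))
    d = np.diag([1.0, 1.0, 1.0, scale])
    # common factor keeps the pencil O(1) for the companion linearization
    norm = np.linalg.norm(c)
    return d @ a0 @ d / norm, d @ a1 @ d / norm, d @ a2 @ d / norm, scale


def partial_wave_spectrum(tensors: PiezoTensorSet, v: float):
    """Eight (alpha, eigenvector) pairs of the depth-wavenumber eigenproblem.

    Returns ``(alphas, vectors)`` with ``alphas`` shape (8,) complex and
    ``vectors`` shape (4, 8); column m is the (u1, u2, u3, phi) polarization of
    partial wave m with depth dependence ``exp(i k alpha_m z)``.
    """
    a0, a1, a2, phi_scale = _quadratic_blocks(tensors, v)
    lhs = np.zeros((8, 8))
    rhs = np.zeros((8, 8))
    lhs[:4, 4:] = np.eye(4)
    lhs[4:, :4] = -a0
    lhs[4:, 4:] = -a1
    rhs[:4, :4] = np.eye(4)
    rhs[4:, 4:] = a2
    alphas, vecs = linalg.eig(lhs, rhs)
    if not np.all(np.isfinite(alphas)):
        raise SawSolverError("defective/degenerate eigensystem; perturb v")
    order = np.argsort(alphas.imag)
    alphas = alphas[order]
    vecs = vecs[:4, order].copy()
    vecs[3] *= phi_scale  # undo the potential-DOF rescaling
    norms = np.linalg.norm(vecs, axis=0)
    if np.any(norms == 0):
        raise SawSolverError("degenerate partial-wave polarization")
    return alphas, vecs / norms


def _pencil(tensors: PiezoTensorSet, v: float):
    a0, a1, a2, phi_scale = _quadratic_blocks(tensors, v)
    d = np.diag([1.0, 1.0, 1.0, phi_scale])

    def f(alpha: complex) -> np.ndarray:
        return a0 + alpha * a1 + alpha * alpha * a2

    return f, d


def _refine_waves(tensors: PiezoTensorSet, v: float, alphas, vecs):
    """Newton-polish depth exponents and recompute polarizations via SVD.

    The linearized eigensolve is accurate to ~1e-8; polishing each root of
    det F(alpha) and taking exact null vectors of F pushes the surface
    boundary residual to near machine precision.  Degenerate exponents
    (e.g. the SV/SH pair of an isotropic solid) share a multi-dimensional
    null space and are resolved with multiple singular vectors.
    """
    f, d = _pencil(tensors, v)

    def det_at(alpha):
        return np.linalg.det(f(alpha))

    # group (nearly) coincident exponents
    groups: list[list[int]] = []
    for m in np.argsort(alphas.real):
        for g in groups:
            if abs(alphas[m] - alphas[g[0]]) < 1e-6 * (1.0 + abs(alphas[m])):
                g.append(m)
                break
        else:
            groups.append([m])

    out_a = np.array(alphas, dtype=complex)
    out_v = np.array(vecs, dtype=complex)
    for g in groups:
        al = complex(np.mean(alphas[g]))
        if len(g) == 1:
            for _ in range(6):
                h = 1e-7 * (1.0 + abs(al))
                dv = (det_at(al + h) - det_at(al - h)) / (2.0 * h)
                if dv == 0:
                    break
                step = det_at(al) / dv
                al = al - step
                if abs(step) < 1e-14 * (1.0 + abs(al)):
                    break
        _, s, vh = np.linalg.svd(f(al))
        for rank, m in enumerate(g):
            out_a[m] = al
            vec = d @ vh[-1 - rank].conj()
            out_v[:, m] = vec / np.linalg.norm(vec)
    return out_a, out_v


def _decaying_waves(tensors: PiezoTensorSet, v: float, refine: bool = True):
    alphas, vecs = partial_wave_spectrum(tensors, v)
    keep = alphas.imag < -_DECAY_IM_TOL
    if keep.sum() != 4:
        raise SawSolverError(
            f"expected 4 decaying partial waves at v={v:.2f} m/s, found "
            f"{int(keep.sum())} (above a bulk-wave cutoff?)")
    alphas, vecs = alphas[keep], vecs[:, keep]
    if refine:
        alphas, vecs = _refine_waves(tensors, v, alphas, vecs)
    return alphas, vecs


def _boundary_matrix(tensors: PiezoTensorSet, alphas, vecs,
                     electric_bc: str) -> np.ndarray:
    """4x4 surface matrix: rows = (T13, T23, T33, D3)/(ik), columns = waves."""
    c = tensors.stiffness_full
    e = tensors.piezo_full
    eps = tensors.permittivity
    b = np.zeros((4, 4), dtype=complex)
    for m in range(4):
        al = alphas[m]
        u = vecs[:3, m]
        phi = vecs[3, m]
        for i in range(3):
            b[i, m] = ((c[i, 2, :, 0] + al * c[i, 2, :, 2]) @ u
                       + (e[0, i, 2] + al * e[2, i, 2]) * phi)
        if electric_bc == "shorted":
            b[3, m] = phi
        else:  # charge-free: D_z = 0
            b[3, m] = ((e[2, :, 0] + al * e[2, :, 2]) @ u
                       - (eps[2, 0] + al * eps[2, 2]) * phi)
    return b


def boundary_determinant(tensors: PiezoTensorSet, v: float,
                         electric_bc: str = "charge_free") -> float:
    """Normalized |det| of the surface boundary-condition matrix at speed v."""
    alphas, vecs = _decaying_waves(tensors, v)
    b = _boundary_matrix(tensors, alphas, vecs, electric_bc)
    scale = np.linalg.norm(b, axis=0)
    scale[scale == 0] = 1.0
    return float(abs(np.linalg.det(b / scale)))


# ---------------------------------------------------------------------------
# Surface-mode search and diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SawMode:
    """A converged free-surface Rayleigh-type SAW mode.

    Depth profiles are parameterized by the (dimensionless) decay exponents:
    ``u_i(z) = sum_m w_m xi_im exp(i k alpha_m z)`` for ``z <= 0`` with
    ``k = 2 pi / wavelength``.  Amplitudes are normalized to unit surface
    normal displacement.
    """

    phase_velocity: float
    alphas: np.ndarray          # (4,) complex depth exponents, Im < 0
    polarizations: np.ndarray   # (4, 4) complex, columns per partial wave
    weights: np.ndarray         # (4,) complex partial-wave amplitudes
    boundary_residual: float
    electric_bc: str

    def displacement(self, z: np.ndarray, wavelength: float) -> np.ndarray:
        """Complex displacement 3-vectors at depths ``z`` (<= 0), shape (n, 3)."""
        k = 2.0 * math.pi / wavelength
        z = np.atleast_1d(np.asarray(z, dtype=float))
        phases = np.exp(1j * k * np.outer(z, self.alphas))  # (n, 4)
        return phases @ (self.weights[:, None] * self.polarizations[:3].T)

    def potential(self, z: np.ndarray, wavelength: float) -> np.ndarray:
        k = 2.0 * math.pi / wavelength
        z = np.atleast_1d(np.asarray(z, dtype=float))
        phases = np.exp(1j * k * np.outer(z, self.alphas))
        return phases @ (self.weights * self.polarizations[3])

    def depth_profile(self, wavelength: float, n: int = 400,
                      depth_wavelengths: float = 2.0):
        """(z, u(z), phi(z)) on a fixed grid over ``depth_wavelengths`` lambda."""
        z = np.linspace(-depth_wavelengths * wavelength, 0.0, n)
        return z, self.displacement(z, wavelength), self.potential(z, wavelength)


def _golden_min(fun, lo: float, hi: float, xtol: float):
    """Plain golden-section minimization; robust for V-shaped |det| profiles."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    while (b - a) > xtol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
    x = 0.5 * (a + b)
    return x, fun(x)


def saw_velocity_free_surface(tensors: PiezoTensorSet,
                              bracket: tuple[float, float],
                              electric_bc: Literal["charge_free", "shorted"] = "charge_free",
                              n_scan: int = 201,
                              det_tol: float = 1e-8) -> SawMode:
    """Locate the Rayleigh surface mode inside a phase-velocity bracket.

    Scans ``n_scan`` velocities, brackets the minimum of the normalized
    boundary determinant and polishes it; fails loudly (with the determinant
    values at the bracket endpoints) when no root lies inside.
    """
    v_lo, v_hi = bracket
    vs = np.linspace(v_lo, v_hi, n_scan)
    dets = np.full(n_scan, np.nan)
    for i, v in enumerate(vs):
        try:
            dets[i] = boundary_determinant(tensors, v, electric_bc)
        except SawSolverError:
            dets[i] = np.nan
    valid = np.isfinite(dets)
    if not np.any(valid):
        raise SawSolverError(
            f"no true-SAW region inside bracket ({v_lo}, {v_hi}) m/s")
    idx = int(np.nanargmin(dets))
    lo = vs[max(idx - 1, 0)]
    hi = vs[min(idx + 1, n_scan - 1)]
    v_root, det_root = _golden_min(
        lambda v: boundary_determinant(tensors, v, electric_bc),
        lo, hi, xtol=1e-12 * max(abs(v_hi), 1.0))
    if det_root > det_tol:
        raise SawSolverError(
            "no surface-mode root in bracket: normalized determinant at "
            f"endpoints |d({v_lo})| = {dets[valid][0]:.3e}, "
            f"|d({v_hi})| = {dets[valid][-1]:.3e}; best {det_root:.3e} "
            f"at {v_root:.2f} m/s exceeds tol {det_tol:.1e}")

    alphas, vecs = _decaying_waves(tensors, v_root)
    b = _boundary_matrix(tensors, alphas, vecs, electric_bc)
    scale = np.linalg.norm(b, axis=0)
    scale[scale == 0] = 1.0
    bn = b / scale
    _, s, vh = np.linalg.svd(bn)
    weights = vh[-1].conj() / scale
    residual = float(s[-1] / s[0])

    uz0 = weights @ vecs[2]
    if abs(uz0) < 1e-12 * np.abs(weights @ vecs[:3].T).max():
        # purely in-plane mode; fall back to the largest surface component
        uz0 = (weights @ vecs[:3].T)[np.argmax(np.abs(weights @ vecs[:3].T))]
    weights = weights / uz0

    return SawMode(phase_velocity=v_root, alphas=alphas, polarizations=vecs,
                   weights=weights, boundary_residual=residual,
                   electric_bc=electric_bc)


def mode_diagnostics(mode: SawMode, wavelength: float,
                     depth_wavelengths: float = 12.0, n: int = 6000) -> dict:
    """Energy confinement and polarization-ellipse diagnostics of a mode.

    The kinetic-energy density is proportional to |u(z)|^2 at fixed omega, so
    the fraction of wave energy within one wavelength of the surface is the
    |u|^2 integral over [-lambda, 0] relative to the full half-space.
    """
    z = np.linspace(-depth_wavelengths * wavelength, 0.0, n)
    u = mode.displacement(z, wavelength)
    dens = np.sum(np.abs(u) ** 2, axis=1)
    total = np.trapezoid(dens, z)
    mask = z >= -wavelength
    within = np.trapezoid(dens[mask], z[mask])
    u0 = mode.displacement(np.array([0.0]), wavelength)[0]
    sagittal = math.hypot(abs(u0[0]), abs(u0[2]))
    transverse = abs(u0[1])
    return {
        "energy_fraction_within_1wl": float(within / total),
        "surface_displacement": u0,
        "sagittal_amplitude": sagittal,
        "transverse_amplitude": transverse,
        "transverse_to_sagittal": float(transverse / sagittal) if sagittal else math.inf,
        "ellipse_axis_ratio": float(abs(u0[0]) / abs(u0[2])) if abs(u0[2]) else math.inf,
    }


def rayleigh_speed_isotropic(c_long: float, c_trans: float) -> float:
    """Real root of Rayleigh's characteristic equation (independent oracle).

    Solves ``(2 - x^2)^2 = 4 sqrt(1 - x^2 ct^2/cl^2) sqrt(1 - x^2)`` for
    ``x = v/ct`` on (0, 1) by bisection.
    """
    ratio2 = (c_trans / c_long) ** 2

    def f(x):
        x2 = x * x
        return (2.0 - x2) ** 2 - 4.0 * math.sqrt(1.0 - x2 * ratio2) * math.sqrt(1.0 - x2)

    return c_trans * optimize.brentq(f, 1e-6, 1.0 - 1e-12, xtol=1e-14)
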