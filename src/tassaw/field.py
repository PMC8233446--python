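"""First-order time-harmonic acoustic fields in the microchannel.

The built-in field is a semi-analytic (tilted-angle) standing wave

    p1(x, y, z) = p_a * cos(k_s * x_r + phase) * exp(-mu * x_r)

with ``x_r = x sin(theta) + y cos(theta)`` the coordinate along the SAW
propagation direction and ``k_s = 2 pi / wavelength``.  ``theta`` is the tilt
of the pressure nodal lines away from the flow axis (x): at ``theta = 0`` the
nodal lines run parallel to the flow and the standing wave spans the channel
width; the node spacing across the width is ``(lambda/2)/cos(theta)``.

The field is uniform along z by default (shallow channel, h << lambda).  The
first-order velocity is ``v1 = -(i / rho0 omega) grad p1`` everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from tassaw.materials import MaterialRecord

log = logging.getLogger(__name__)


class FieldError(ValueError):
    """Bad field configuration or evaluation outside the domain."""


@dataclass(frozen=True)
class ChannelGeometry:
    """Rectangular channel footprint [0, L] x [0, w], height h from substrate."""

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise FieldError("channel dimensions must be positive")

    def contains(self, x: float, y: float, z: float) -> bool:
        return (0.0 <= x <= self.length and 0.0 <= y <= self.width
                and 0.0 <= z <= self.height)


class FirstOrderField:
    """Complex time-harmonic pressure/velocity field of a (ta)SSAW channel.

    Parameters
    ----------
    p_a : pressure amplitude, Pa.
    wavelength : SAW wavelength (sets the standing-wave period), m.
    tilt_deg : nodal-line tilt from the flow axis, degrees, |theta| <= 90.
    geometry : channel box.
    fluid : fluid record (density, sound speed; used by Eq.-9-type relation).
    frequency : drive frequency, Hz.  Default ``None`` makes the field a
        self-consistent acoustic standing wave (omega = k_s c0, zero Helmholtz
        residual).  Pass the SAW drive frequency (c_sub/lambda) for device
        runs; the z-uniform profile is then a shallow-channel approximation.
    phase : phase offset of the cosine along x_r, rad.
    damping : dimensionless damping factor gamma of k = (1 + i gamma) omega/c0
        (default 0; bulk viscous damping is negligible at MHz in water).
    attenuation : optional amplitude decay rate along x_r, 1/m.
    """

    def __init__(self, p_a: float, wavelength: float, tilt_deg: float,
                 geometry: ChannelGeometry, fluid: MaterialRecord,
                 frequency: Optional[float] = None, phase: float = 0.0,
                 damping: float = 0.0, attenuation: float = 0.0):
        if wavelength <= 0:
            raise FieldError("wavelength must be positive")
        if not -90.0 <= tilt_deg <= 90.0:
            raise FieldError("|tilt| must be <= 90 degrees")
        if fluid.sound_speed is None:
            raise FieldError("fluid needs a sound speed")
        self.p_a = float(p_a)
        self.wavelength = float(wavelength)
        self.tilt_deg = float(tilt_deg)
        self.geometry = geometry
        self.fluid = fluid
        self.phase = float(phase)
        self.damping = float(damping)
        self.attenuation = float(attenuation)
        self.k_s = 2.0 * math.pi / self.wavelength
        self.rho0 = fluid.density
        self.c0 = fluid.sound_speed
        if frequency is None:
            self.omega = self.k_s * self.c0
        else:
            if frequency <= 0:
                raise FieldError("frequency must be positive")
            self.omega = 2.0 * math.pi * frequency
        t = math.radians(self.tilt_deg)
        # unit vector along the SAW propagation direction (across the nodal lines)
        self._dir = np.array([math.sin(t), math.cos(t), 0.0])

    # -- helpers -----------------------------------------------------------

    @property
    def frequency(self) -> float:
        return self.omega / (2.0 * math.pi)

    @property
    def wavenumber(self) -> complex:
        """Lossy fluid wavenumber metadata k = (1 + i gamma) omega / c0."""
        return (1.0 + 1j * self.damping) * self.omega / self.c0

    @property
    def velocity_amplitude(self) -> float:
        """Tangential velocity amplitude p_a k_s / (rho0 omega)."""
        return self.p_a * self.k_s / (self.rho0 * self.omega)

    @property
    def energy_density(self) -> float:
        """Time-averaged acoustic energy density E_ac = p_a^2/(4 rho0 c0^2)."""
        return self.p_a ** 2 / (4.0 * self.rho0 * self.c0 ** 2)

    def x_r(self, x, y):
        return self._dir[0] * np.asarray(x) + self._dir[1] * np.asarray(y)

    # -- field evaluation --------------------------------------------------

    def pressure(self, x, y, z=0.0) -> np.ndarray:
        xr = self.x_r(x, y)
        env = np.exp(-self.attenuation * xr) if self.attenuation else 1.0
        return (self.p_a * np.cos(self.k_s * xr + self.phase) * env
                ).astype(complex)

    def grad_pressure(self, x, y, z=0.0) -> np.ndarray:
        """Complex pressure gradient, shape (..., 3)."""
        xr = self.x_r(x, y)
        arg = self.k_s * xr + self.phase
        env = np.exp(-self.attenuation * xr) if self.attenuation else 1.0
        dpdxr = self.p_a * env * (-self.k_s * np.sin(arg)
                                  - self.attenuation * np.cos(arg))
        return np.multiply.outer(dpdxr, self._dir).astype(complex)

    def hessian_pressure(self, x, y, z=0.0) -> np.ndarray:
        """Complex Hessian of p1, shape (..., 3, 3)."""
        xr = self.x_r(x, y)
        arg = self.k_s * xr + self.phase
        env = np.exp(-self.attenuation * xr) if self.attenuation else 1.0
        d2 = self.p_a * env * (
            (self.attenuation ** 2 - self.k_s ** 2) * np.cos(arg)
            + 2.0 * self.attenuation * self.k_s * np.sin(arg))
        outer = np.outer(self._dir, self._dir)
        return np.multiply.outer(d2, outer).astype(complex)

    def velocity(self, x, y, z=0.0) -> np.ndarray:
        """First-order velocity v1 = -(i / rho0 omega) grad p1, shape (..., 3)."""
        return -1j / (self.rho0 * self.omega) * self.grad_pressure(x, y, z)

    def velocity_jacobian(self, x, y, z=0.0) -> np.ndarray:
        """Jacobian dv1_i/dx_j, shape (..., 3, 3)."""
        return -1j / (self.rho0 * self.omega) * self.hessian_pressure(x, y, z)

    def helmholtz_residual(self, x, y, z=0.0, k: Optional[float] = None) -> float:
        """Max of |lap p1 + k^2 p1| / (k^2 |p1|_max) over the given points.

        ``k`` defaults to the field's spatial wavenumber k_s, for which the
        built-in analytic field is an exact Helmholtz solution.
        """
        kk = self.k_s if k is None else k
        hess = self.hessian_pressure(x, y, z)
        lap = np.trace(hess, axis1=-2, axis2=-1)
        p = self.pressure(x, y, z)
        denom = abs(kk) ** 2 * max(np.max(np.abs(p)), 1e-300)
        return float(np.max(np.abs(lap + kk ** 2 * p)) / denom)

    # -- nodal structure ---------------------------------------------------

    def _line_loci(self, offsets: np.ndarray) -> list[dict]:
        """Clip the lines x_r = offset to the channel footprint."""
        geom = self.geometry
        d = self._dir
        # line direction (along nodal lines) is perpendicular to d in-plane
        ld = np.array([d[1], -d[0]])
        corners = [(0.0, 0.0), (geom.length, 0.0), (0.0, geom.width),
                   (geom.length, geom.width)]
        xr_lo = min(self.x_r(x, y) for x, y in corners)
        xr_hi = max(self.x_r(x, y) for x, y in corners)
        out = []
        for off in offsets:
            if not xr_lo - 1e-15 <= off <= xr_hi + 1e-15:
                continue
            # a point on the line
            p0 = np.array([d[0], d[1]]) * off
            ts = []
            for (lo, hi, comp) in ((0.0, geom.length, 0), (0.0, geom.width, 1)):
                if abs(ld[comp]) > 1e-15:
                    ts.append((lo - p0[comp]) / ld[comp])
                    ts.append((hi - p0[comp]) / ld[comp])
            pts = []
            for t in ts:
                q = p0 + t * ld
                if (-1e-12 <= q[0] <= geom.length + 1e-12
                        and -1e-12 <= q[1] <= geom.width + 1e-12):
                    pts.append(q)
            if len(pts) < 2:
                continue
            pts = sorted(pts, key=lambda q: (q[0], q[1]))
            start, end = pts[0], pts[-1]
            if np.linalg.norm(end - start) < 1e-12:
                continue
            out.append({"x_r": float(off),
                        "start": (float(start[0]), float(start[1])),
                        "end": (float(end[0]), float(end[1]))})
        return out

    def nodal_lines(self, plane_z: float = 0.0) -> list[dict]:
        """Pressure-node loci (x_r at odd quarter wavelengths), ordered along x."""
        return self._lines_at(0.5)

    def antinodal_lines(self, plane_z: float = 0.0) -> list[dict]:
        """Pressure-antinode loci, interleaving the nodes exactly halfway."""
        return self._lines_at(0.0)

    def _lines_at(self, half_offset: float) -> list[dict]:
        geom = self.geometry
        corners = [(0.0, 0.0), (geom.length, 0.0), (0.0, geom.width),
                   (geom.length, geom.width)]
        xr_lo = min(self.x_r(x, y) for x, y in corners)
        xr_hi = max(self.x_r(x, y) for x, y in corners)
        half = 0.5 * self.wavelength
        # cos(k xr + phase) extrema/zeros: k xr + phase = n pi (+ pi/2 for nodes)
        base = (-self.phase / self.k_s) + half_offset * half
        n_lo = math.floor((xr_lo - base) / half) - 1
        n_hi = math.ceil((xr_hi - base) / half) + 1
        offsets = base + half * np.arange(n_lo, n_hi + 1)
        lines = self._line_loci(offsets)
        lines.sort(key=lambda rec: (rec["start"][0] + rec["end"][0]))
        return lines


def make_tassaw_field(p_a: float, wavelength: float, tilt_deg: float,
                      geometry: ChannelGeometry, fluid: MaterialRecord,
                      frequency: Optional[float] = None, phase: float = 0.0,
                      damping: float = 0.0, attenuation: float = 0.0,
                      z_profile: str = "uniform") -> FirstOrderField:
    """Build the semi-analytic (ta)SSAW standing-wave field.

    Warns when the shallow-channel assumption (h/lambda <= 0.2) behind the
    uniform z-profile is strained and logs a hard warning above h/lambda=0.5.
    """
    if z_profile != "uniform":
        raise FieldError(f"unknown z_profile {z_profile!r}")
    ratio = geometry.height / wavelength
    if ratio > 0.5:
        log.error("h/lambda = %.2f > 0.5: uniform z-profile is not a valid "
                  "approximation for this geometry", ratio)
    elif ratio > 0.2:
        log.warning("h/lambda = %.2f > 0.2: uniform z-profile approximation "
                    "is strained", ratio)
    return FirstOrderField(p_a, wavelength, tilt_deg, geometry, fluid,
                           frequency=frequency, phase=phase, damping=damping,
                           attenuation=attenuation)


def gridded_velocity_from_pressure(p: np.ndarray, spacings, rho0: float,
                                   omega: float) -> np.ndarray:
    """Velocity from a gridded pressure by 2nd-order central differences.

    ``p`` is a complex array over a regular grid; ``spacings`` gives the grid
    step per axis.  Returns an array of shape ``p.shape + (ndim,)``.
    """
    if rho0 <= 0 or omega <= 0:
        raise FieldError("need rho0 > 0 and omega > 0")
    grads = np.gradient(p, *spacings)
    if p.ndim == 1:
        grads = [grads]
    return np.stack([-1j / (rho0 * omega) * g for g in grads], axis=-1)
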