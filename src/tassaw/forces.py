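"""Acoustic radiation force with viscous scattering corrections, and Stokes drag.

The radiation force on a small spherical particle (radius r << lambda) is

    F_rad = -pi r^3 [ (2 kappa_f / 3) Re(f1* p1* grad p1)
                      - rho_f Re(f2* (v1* . grad) v1) ]

with monopole coefficient ``f1 = 1 - kappa_p/kappa_f`` and viscous dipole
coefficient ``f2 = 2 (1 - L)(rho~ - 1) / (2 rho~ + 1 - 3 L)``,
``L = -(3/2) [1 + i (1 + d~)] d~``, ``d~ = delta_nu / r``.

In the inviscid limit ``3 (f1/3 + Re f2 / 2)`` equals the acoustic contrast
factor, so positive-contrast particles collect at pressure nodes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from tassaw.field import FirstOrderField
from tassaw.materials import MaterialRecord, boundary_layer_thickness


class ForceError(ValueError):
    pass


@dataclass(frozen=True)
class ParticleSpec:
    """Spherical particle: radius, density, compressibility, label."""

    radius: float
    density: float
    compressibility: float
    label: str = "particle"

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.density <= 0 or self.compressibility <= 0:
            raise ForceError(f"{self.label}: radius/density/compressibility "
                             "must all be positive")

    @property
    def mass(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius ** 3 * self.density

    @staticmethod
    def from_material(mat: MaterialRecord, diameter: float | None = None,
                      label: str | None = None) -> "ParticleSpec":
        d = diameter if diameter is not None else mat.diameter
        if d is None:
            raise ForceError(f"{mat.name}: no diameter given")
        kappa = mat.compressibility
        if kappa is None:
            kappa = mat.derived_compressibility()
        return ParticleSpec(radius=0.5 * d, density=mat.density,
                            compressibility=kappa,
                            label=label or f"{mat.name}_{d * 1e6:g}um")

    def check_long_wavelength(self, wavelength: float) -> None:
        if self.radius / wavelength > 0.05:
            warnings.warn(
                f"{self.label}: r/lambda = {self.radius / wavelength:.3f} "
                "> 0.05 strains the small-particle assumption", stacklevel=2)


def scattering_f1(kappa_ratio: float) -> complex:
    """Monopole coefficient f1 = 1 - kappa_p/kappa_f (real)."""
    if kappa_ratio < 0:
        raise ForceError("compressibility ratio must be >= 0")
    return complex(1.0 - kappa_ratio)


def viscous_lambda(delta_ratio: float) -> complex:
    """L(d~) = -(3/2) [1 + i (1 + d~)] d~."""
    if delta_ratio < 0:
        raise ForceError("delta_nu/r must be >= 0")
    return -1.5 * (1.0 + 1j * (1.0 + delta_ratio)) * delta_ratio


def scattering_f2(rho_ratio: float, delta_ratio: float) -> complex:
    """Viscous dipole coefficient f2(rho~, d~)."""
    if rho_ratio <= 0:
        raise ForceError("density ratio must be positive")
    lam = viscous_lambda(delta_ratio)
    return (2.0 * (1.0 - lam) * (rho_ratio - 1.0)
            / (2.0 * rho_ratio + 1.0 - 3.0 * lam))


def radiation_force(field1: FirstOrderField, particle: ParticleSpec,
                    position, fluid: MaterialRecord,
                    delta_nu: float | None = None,
                    check_bounds: bool = True) -> np.ndarray:
    """Radiation force (N) on ``particle`` at ``position`` in ``field1``.

    ``delta_nu`` overrides the boundary-layer thickness (computed from the
    fluid viscosity at the field frequency by default; pass 0 for the
    inviscid limit).  ``check_bounds=False`` allows evaluation of the analytic
    field just outside the channel box (used by integrator trial steps).
    """
    x, y, z = position
    if check_bounds and not field1.geometry.contains(x, y, z):
        for name, val, hi in (("x", x, field1.geometry.length),
                              ("y", y, field1.geometry.width),
                              ("z", z, field1.geometry.height)):
            if not 0.0 <= val <= hi:
                raise ForceError(
                    f"position {name} = {val:.3e} outside [0, {hi:.3e}]")
    kappa_f = fluid.compressibility
    if kappa_f is None:
        kappa_f = fluid.derived_compressibility()
    if delta_nu is None:
        if fluid.dynamic_viscosity is None:
            delta_nu = 0.0
        else:
            delta_nu = boundary_layer_thickness(
                fluid.dynamic_viscosity, fluid.density, field1.frequency)
    f1 = scattering_f1(particle.compressibility / kappa_f)
    f2 = scattering_f2(particle.density / fluid.density,
                       delta_nu / particle.radius)

    p = field1.pressure(x, y, z)
    gp = field1.grad_pressure(x, y, z)
    v = field1.velocity(x, y, z)
    jac = field1.velocity_jacobian(x, y, z)
    # (v1* . grad) v1, i.e. J_ij v_j*
    conv = jac @ np.conj(v)
    term1 = (2.0 * kappa_f / 3.0) * np.real(np.conj(f1) * np.conj(p) * gp)
    term2 = fluid.density * np.real(np.conj(f2) * conv)
    return -math.pi * particle.radius ** 3 * (term1 - term2)


def standing_wave_force_amplitude(field1: FirstOrderField,
                                  particle: ParticleSpec,
                                  fluid: MaterialRecord,
                                  delta_nu: float = 0.0) -> float:
    """Closed-form amplitude 4 pi Phi r^3 k E_ac of the standing-wave force.

    ``Phi = f1/3 + Re(f2)/2``; the force along the standing-wave axis is this
    amplitude times ``sin(2 k x_r)`` (inviscid limit).
    """
    kappa_f = fluid.compressibility or fluid.derived_compressibility()
    f1 = scattering_f1(particle.compressibility / kappa_f).real
    f2 = scattering_f2(particle.density / fluid.density,
                       delta_nu / particle.radius)
    phi_factor = f1 / 3.0 + f2.real / 2.0
    return (4.0 * math.pi * phi_factor * particle.radius ** 3
            * field1.k_s * field1.energy_density)


def stokes_drag(v_fluid, v_particle, radius: float, eta: float) -> np.ndarray:
    """F_drag = 6 pi eta r (v_fluid - v_particle)."""
    if radius <= 0 or eta <= 0:
        raise ForceError("radius and viscosity must be positive")
    return (6.0 * math.pi * eta * radius
            * (np.asarray(v_fluid, dtype=float) - np.asarray(v_particle, dtype=float)))
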