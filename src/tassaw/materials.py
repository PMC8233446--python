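"""Material records, derived acoustic quantities and tensor rotation.

The built-in library (``data/materials.yaml``) stores one record per medium in
SI units.  Piezoelectric single-crystal constants live in a separate data file
and are rotated to arbitrary plate frames with Bond matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


class MaterialError(ValueError):
    """Invalid material data or arguments outside the physical domain."""


# ---------------------------------------------------------------------------
# Material records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialRecord:
    """Properties of one medium (fluid, particle/cell, wall or substrate).

    All quantities are SI.  ``compressibility`` is the stored (authoritative)
    value; use :func:`compressibility_from_rho_c` to recompute it from density
    and sound speed.
    """

    name: str
    kind: str  # fluid | particle | cell | wall | substrate
    density: float
    sound_speed: Optional[float] = None
    dynamic_viscosity: Optional[float] = None
    bulk_viscosity: Optional[float] = None
    compressibility: Optional[float] = None
    poisson: Optional[float] = None
    diameter: Optional[float] = None
    attenuation_db_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise MaterialError(f"{self.name}: density must be positive")
        for attr in ("sound_speed", "compressibility", "dynamic_viscosity",
                     "diameter"):
            val = getattr(self, attr)
            if val is not None and val <= 0:
                raise MaterialError(f"{self.name}: {attr} must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        if self.dynamic_viscosity is None:
            raise MaterialError(f"{self.name}: no viscosity defined")
        return self.dynamic_viscosity / self.density

    def derived_compressibility(self) -> float:
        """1/(rho c^2); the stored value takes precedence when present."""
        if self.sound_speed is None:
            raise MaterialError(f"{self.name}: no sound speed defined")
        return compressibility_from_rho_c(self.density, self.sound_speed)


_FIELD_MAP = {
    "density_kg_m3": "density",
    "sound_speed_m_s": "sound_speed",
    "dynamic_viscosity_pa_s": "dynamic_viscosity",
    "bulk_viscosity_pa_s": "bulk_viscosity",
    "compressibility_per_pa": "compressibility",
    "poisson_ratio": "poisson",
    "diameter_m": "diameter",
    "attenuation_db_cm": "attenuation_db_cm",
}


def _load_yaml_resource(filename: str) -> dict:
    ref = resources.files("tassaw").joinpath("data", filename)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


_LIBRARY_CACHE: dict[str, MaterialRecord] = {}


def load_library() -> dict[str, MaterialRecord]:
    """Return the full built-in material library keyed by name."""
    if not _LIBRARY_CACHE:
        raw = _load_yaml_resource("materials.yaml")
        for name, rec in raw.items():
            kwargs = {"name": name, "kind": rec.pop("kind")}
            for key, val in rec.items():
                kwargs[_FIELD_MAP[key]] = float(val)
            _LIBRARY_CACHE[name] = MaterialRecord(**kwargs)
    return dict(_LIBRARY_CACHE)


def load_material(name: str) -> MaterialRecord:
    lib = load_library()
    if name not in lib:
        raise MaterialError(
            f"unknown material {name!r}; available: {sorted(lib)}")
    return lib[name]


def consistency_report(rec: MaterialRecord, rtol: float = 0.01) -> dict:
    """Compare the stored compressibility against the 1/(rho c^2) recomputation.

    Returns a dict with both values and a ``consistent`` flag; emits a warning
    when they disagree beyond ``rtol`` (the stored value stays authoritative).
    """
    out = {"name": rec.name, "stored": rec.compressibility, "derived": None,
           "consistent": None}
    if rec.compressibility is None or rec.sound_speed is None:
        return out
    derived = rec.derived_compressibility()
    out["derived"] = derived
    out["consistent"] = bool(
        abs(derived - rec.compressibility) <= rtol * rec.compressibility)
    if not out["consistent"]:
        warnings.warn(
            f"{rec.name}: stored compressibility {rec.compressibility:.3e} "
            f"differs from 1/(rho c^2) = {derived:.3e}; stored value is used",
            stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Scalar derived quantities
# ---------------------------------------------------------------------------

def compressibility_from_rho_c(rho: float, c: float) -> float:
    """kappa = 1/(rho c^2)."""
    if rho <= 0 or c <= 0:
        raise MaterialError("density and sound speed must be positive")
    return 1.0 / (rho * c * c)


def compressibility_landau(sigma: float, rho: float, c: float) -> float:
    """Elastic-sphere compressibility 3(1-sigma)/(1+sigma) / (rho c^2).

    ``sigma`` is the Poisson ratio; valid on (-1, 0.5].  At sigma = 0.5 the
    prefactor is 1 and the expression reduces to 1/(rho c^2).
    """
    if not (-1.0 < sigma <= 0.5):
        raise MaterialError(f"Poisson ratio {sigma} outside (-1, 0.5]")
    return 3.0 * (1.0 - sigma) / (1.0 + sigma) * compressibility_from_rho_c(rho, c)


def contrast_factor(rho_p: float, kappa_p: float,
                    rho_f: float, kappa_f: float) -> float:
    """Acoustic contrast factor (5 rho_p - 2 rho_f)/(2 rho_p + rho_f) - kappa_p/kappa_f.

    Positive values drive particles toward pressure nodes.
    """
    if min(rho_p, kappa_p, rho_f, kappa_f) <= 0:
        raise MaterialError("all contrast-factor arguments must be positive")
    return (5.0 * rho_p - 2.0 * rho_f) / (2.0 * rho_p + rho_f) - kappa_p / kappa_f


def boundary_layer_thickness(eta: float, rho: float, freq: float) -> float:
    """Viscous boundary-layer thickness delta = sqrt(2 nu / omega)."""
    if eta < 0 or rho <= 0 or freq <= 0:
        raise MaterialError("need eta >= 0, rho > 0, freq > 0")
    omega = 2.0 * math.pi * freq
    return math.sqrt(2.0 * (eta / rho) / omega)


def voltage_to_dbm(volts: float, volts_ref: float, dbm_ref: float,
                   rounding: str = "nearest") -> float:
    """Convert a drive voltage to input power in dBm via P ~ V^2.

    The (volts_ref, dbm_ref) pair is a per-device calibration; no global
    calibration exists.  ``rounding`` is ``"nearest"`` (integer dBm, the
    default) or ``"none"``.
    """
    if volts <= 0 or volts_ref <= 0:
        raise MaterialError("voltages must be positive")
    dbm = dbm_ref + 20.0 * math.log10(volts / volts_ref)
    if rounding == "nearest":
        return float(math.floor(dbm + 0.5))
    if rounding == "none":
        return dbm
    raise MaterialError(f"unknown rounding mode {rounding!r}")


def frequency_from_wavelength(c_sub: float, wavelength: float) -> float:
    """SAW frequency f = c_sub / lambda."""
    if c_sub <= 0 or wavelength <= 0:
        raise MaterialError("substrate speed and wavelength must be positive")
    return c_sub / wavelength


# ---------------------------------------------------------------------------
# Piezoelectric tensors and crystallographic cuts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiezoTensorSet:
    """Stiffness (6x6 Voigt, Pa), piezo (3x6, C/m^2), permittivity (3x3, F/m)."""

    stiffness: np.ndarray
    piezo: np.ndarray
    permittivity: np.ndarray
    density: float

    def __post_init__(self) -> None:
        c = np.asarray(self.stiffness, dtype=float)
        e = np.asarray(self.piezo, dtype=float)
        eps = np.asarray(self.permittivity, dtype=float)
        if c.shape != (6, 6) or e.shape != (3, 6) or eps.shape != (3, 3):
            raise MaterialError("tensor shapes must be (6,6), (3,6), (3,3)")
        if not np.allclose(c, c.T, rtol=1e-8, atol=1e-3):
            raise MaterialError("stiffness matrix must be symmetric")
        if not np.allclose(eps, eps.T, rtol=1e-8, atol=1e-20):
            raise MaterialError("permittivity must be symmetric")
        if np.any(np.linalg.eigvalsh(c) <= 0):
            raise MaterialError("stiffness matrix must be positive definite")
        if np.any(np.linalg.eigvalsh(eps) <= 0):
            raise MaterialError("permittivity must be positive definite")
        if self.density <= 0:
            raise MaterialError("density must be positive")
        object.__setattr__(self, "stiffness", c)
        object.__setattr__(self, "piezo", e)
        object.__setattr__(self, "permittivity", eps)

    @property
    def stiffness_full(self) -> np.ndarray:
        """Full c_ijkl (3,3,3,3) rebuilt from the Voigt matrix."""
        c4 = np.empty((3, 3, 3, 3))
        for a, (i, j) in enumerate(_VOIGT_PAIRS):
            for b, (k, l) in enumerate(_VOIGT_PAIRS):
                v = self.stiffness[a, b]
                c4[i, j, k, l] = c4[j, i, k, l] = v
                c4[i, j, l, k] = c4[j, i, l, k] = v
        return c4

    @property
    def piezo_full(self) -> np.ndarray:
        """Full e_kij (3,3,3) rebuilt from the 3x6 matrix."""
        e3 = np.empty((3, 3, 3))
        for a, (i, j) in enumerate(_VOIGT_PAIRS):
            e3[:, i, j] = self.piezo[:, a]
            e3[:, j, i] = self.piezo[:, a]
        return e3


@dataclass(frozen=True)
class CrystalCut:
    """Proper rotation taking crystal-frame components to the plate frame.

    Plate frame convention: x = propagation direction, z = outward surface
    normal.  Row i of ``rotation`` is plate basis vector i expressed in
    crystal coordinates.
    """

    rotation: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.rotation, dtype=float)
        if a.shape != (3, 3):
            raise MaterialError("rotation must be a 3x3 matrix")
        for col in range(3):
            if abs(np.linalg.norm(a[:, col]) - 1.0) > 1e-12:
                raise MaterialError(
                    f"rotation column {col} is not unit-norm to 1e-12")
        if not np.allclose(a @ a.T, np.eye(3), atol=1e-12):
            off = a @ a.T - np.eye(3)
            col = int(np.argmax(np.abs(off).sum(axis=0)))
            raise MaterialError(
                f"rotation columns not orthonormal (worst column {col})")
        if np.linalg.det(a) < 0:
            raise MaterialError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", a)

    @staticmethod
    def identity() -> "CrystalCut":
        return CrystalCut(np.eye(3))

    @staticmethod
    def about_x(angle_deg: float) -> "CrystalCut":
        """Frame rotation by ``angle_deg`` about the crystal X axis."""
        t = math.radians(angle_deg)
        c, s = math.cos(t), math.sin(t)
        return CrystalCut(np.array([[1.0, 0.0, 0.0],
                                    [0.0, c, s],
                                    [0.0, -s, c]]))

    @staticmethod
    def rotated_y_cut(angle_deg: float, sign: int = -1,
                      flip_propagation: bool = False) -> "CrystalCut":
        """Rotated Y-cut, X-propagating plate (e.g. ``angle_deg=128``).

        The plate normal is the crystal +Y axis rotated about the X axis by
        ``sign * (angle_deg - 90)`` degrees; propagation is along crystal X.
        The default ``sign=-1`` is the convention that reproduces the known
        Rayleigh speed of the 128-degree cut (validated by the SAW-speed
        check in :mod:`tassaw.substrate`); ``sign=+1`` selects the mirror
        convention.  ``flip_propagation`` reverses x (and y, keeping the
        frame right-handed).
        """
        if sign not in (-1, 1):
            raise MaterialError("sign must be +1 or -1")
        mu = math.radians(sign * (angle_deg - 90.0))
        zc = np.array([0.0, math.cos(mu), math.sin(mu)])
        xc = np.array([1.0, 0.0, 0.0])
        yc = np.cross(zc, xc)
        if flip_propagation:
            xc, yc = -xc, -yc
        return CrystalCut(np.vstack([xc, yc, zc]))

    def inverse(self) -> "CrystalCut":
        return CrystalCut(self.rotation.T)


def bond_matrix(a: np.ndarray) -> np.ndarray:
    """6x6 Bond stress-transformation matrix of the 3x3 rotation ``a``."""
    a = np.asarray(a, dtype=float)
    m = np.empty((6, 6))
    # normal-stress rows
    for r, i in enumerate(range(3)):
        m[r, :3] = a[i, :] ** 2
        m[r, 3] = 2.0 * a[i, 1] * a[i, 2]
        m[r, 4] = 2.0 * a[i, 2] * a[i, 0]
        m[r, 5] = 2.0 * a[i, 0] * a[i, 1]
    # shear rows follow Voigt order (23, 13, 12)
    pairs = [(1, 2), (0, 2), (0, 1)]
    for r, (i, j) in enumerate(pairs, start=3):
        m[r, :3] = a[i, :] * a[j, :]
        m[r, 3] = a[i, 1] * a[j, 2] + a[i, 2] * a[j, 1]
        m[r, 4] = a[i, 0] * a[j, 2] + a[i, 2] * a[j, 0]
        m[r, 5] = a[i, 0] * a[j, 1] + a[i, 1] * a[j, 0]
    return m


def rotate_tensors(tensors: PiezoTensorSet, cut: CrystalCut) -> PiezoTensorSet:
    """Rotate stiffness/piezo/permittivity into the plate frame of ``cut``.

    c' = M c M^T, e' = a e M^T, eps' = a eps a^T with a the 3x3 rotation and
    M its Bond matrix.
    """
    a = cut.rotation
    m = bond_matrix(a)
    return PiezoTensorSet(
        stiffness=m @ tensors.stiffness @ m.T,
        piezo=a @ tensors.piezo @ m.T,
        permittivity=a @ tensors.permittivity @ a.T,
        density=tensors.density,
    )


def load_linbo3_crystal() -> PiezoTensorSet:
    """Single-crystal LiNbO3 constants (class 3m) in the crystal frame."""
    raw = _load_yaml_resource("linbo3_crystal.yaml")
    cs = {k: float(v) for k, v in raw["stiffness_pa"].items()}
    c11, c12, c13, c14 = cs["c11"], cs["c12"], cs["c13"], cs["c14"]
    c33, c44 = cs["c33"], cs["c44"]
    c66 = 0.5 * (c11 - c12)
    stiffness = np.array([
        [c11, c12, c13, c14, 0.0, 0.0],
        [c12, c11, c13, -c14, 0.0, 0.0],
        [c13, c13, c33, 0.0, 0.0, 0.0],
        [c14, -c14, 0.0, c44, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, c44, c14],
        [0.0, 0.0, 0.0, 0.0, c14, c66],
    ])
    es = {k: float(v) for k, v in raw["piezo_c_m2"].items()}
    e15, e22, e31, e33 = es["e15"], es["e22"], es["e31"], es["e33"]
    piezo = np.array([
        [0.0, 0.0, 0.0, 0.0, e15, -e22],
        [-e22, e22, 0.0, e15, 0.0, 0.0],
        [e31, e31, e33, 0.0, 0.0, 0.0],
    ])
    ep = raw["relative_permittivity_strain"]
    permittivity = EPS0 * np.diag([float(ep["eps11"]), float(ep["eps11"]),
                                   float(ep["eps33"])])
    return PiezoTensorSet(stiffness=stiffness, piezo=piezo,
                          permittivity=permittivity,
                          density=float(raw["density_kg_m3"]))


def isotropic_tensors(rho: float, c_long: float, c_trans: float,
                      eps_rel: float = 1.0) -> PiezoTensorSet:
    """Non-piezoelectric isotropic solid (useful as a classical-limit check)."""
    mu = rho * c_trans ** 2
    lam = rho * c_long ** 2 - 2.0 * mu
    c11 = lam + 2.0 * mu
    stiffness = np.array([
        [c11, lam, lam, 0, 0, 0],
        [lam, c11, lam, 0, 0, 0],
        [lam, lam, c11, 0, 0, 0],
        [0, 0, 0, mu, 0, 0],
        [0, 0, 0, 0, mu, 0],
        [0, 0, 0, 0, 0, mu],
    ], dtype=float)
    return PiezoTensorSet(stiffness=stiffness, piezo=np.zeros((3, 6)),
                          permittivity=EPS0 * eps_rel * np.eye(3), density=rho)


def linbo3_128yx_tensors(sign: int = -1) -> PiezoTensorSet:
    """LiNbO3 constants rotated to the 128-degree Y-cut, X-propagating frame."""
    return rotate_tensors(load_linbo3_crystal(),
                          CrystalCut.rotated_y_cut(128.0, sign=sign))


def without_piezo(tensors: PiezoTensorSet) -> PiezoTensorSet:
    """Same elastic constants with the piezoelectric coupling switched off."""
    return replace(tensors, piezo=np.zeros((3, 6)))
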