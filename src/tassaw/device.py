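"""Multi-stage separator devices: focusing -> realignment -> separation.

A device is a chain of stages along a straight channel (x = flow axis).  The
focusing stage is a narrow channel (width lambda/2) carrying a conventional
standing wave with a single pressure nodal line along its center; the
realignment stage merges a side flow to redirect the particle-laden stream
parallel to the sidewall; the separation stage carries the tilted-angle
standing wave.  Drive voltage maps linearly to pressure amplitude through a
per-stage calibration pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from tassaw.field import ChannelGeometry, FirstOrderField, make_tassaw_field
from tassaw.forces import ParticleSpec
from tassaw.materials import MaterialRecord, load_material
from tassaw.tracing import Trajectory, separation_metrics, trace


class DeviceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Linear voltage -> pressure-amplitude map anchored at one pair."""

    voltage: float
    pressure: float

    def __post_init__(self) -> None:
        if self.voltage <= 0 or self.pressure <= 0:
            raise DeviceError("calibration pair must be positive")


def calibrate_amplitude(voltage: float, calibration: Optional[Calibration]) -> float:
    """p_a = p_cal * (V / V_cal); calibration is per device/stage."""
    if calibration is None:
        raise DeviceError("no amplitude calibration configured for this stage")
    if voltage < 0:
        raise DeviceError("voltage must be non-negative")
    return calibration.pressure * voltage / calibration.voltage


@dataclass(frozen=True)
class StageConfig:
    """One stage of the device chain."""

    kind: str                    # focusing | realignment | separation
    length: float
    width: float
    tilt_deg: float = 0.0
    drive_voltage: float = 0.0
    calibration: Optional[Calibration] = None
    axial_flow: float = 0.0      # imposed inlet velocity (focusing stage), m/s
    side_flow: float = 0.0       # side-inlet velocity (realignment only), m/s
    side_inlet_width: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("focusing", "realignment", "separation"):
            raise DeviceError(f"unknown stage kind {self.kind!r}")
        if self.length <= 0 or self.width <= 0:
            raise DeviceError("stage dimensions must be positive")

    @property
    def pressure_amplitude(self) -> float:
        if self.drive_voltage == 0.0:
            return 0.0
        return calibrate_amplitude(self.drive_voltage, self.calibration)


@dataclass(frozen=True)
class DeviceConfig:
    """Ordered stages plus shared channel/fluid/particle data."""

    stages: tuple[StageConfig, ...]
    height: float
    fluid: MaterialRecord
    particles: tuple[ParticleSpec, ...]
    frequency: float
    wavelength: float
    name: str = "device"
    release_offsets: tuple[float, ...] = ()
    trace_height: float = 20e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise DeviceError("channel height must be positive")
        if not self.stages:
            raise DeviceError("device needs at least one stage")
        for st in self.stages:
            if st.kind == "focusing" and abs(
                    st.width - self.wavelength / 2.0) > 1e-9:
                raise DeviceError(
                    "focusing stage width must equal lambda/2 "
                    f"({self.wavelength / 2.0:.3e} m), got {st.width:.3e}")


# ---------------------------------------------------------------------------
# Flow composition
# ---------------------------------------------------------------------------

def realignment_side_angle(q_main: float, u_main: float, theta_deg: float,
                           q_side: float, u_side: float) -> float:
    """Side-flow direction (deg from the wall) that makes the merge axial.

    Momentum-flux-weighted vector addition: the transverse momentum flux of
    the main stream entering at ``theta_deg`` must be cancelled by the side
    stream, ``q_s u_s sin(beta) = -q_m u_m sin(theta)``.
    """
    s = -q_main * u_main * math.sin(math.radians(theta_deg)) / (q_side * u_side)
    if abs(s) > 1.0:
        raise DeviceError("side flow too weak to realign the main stream")
    return math.degrees(math.asin(s))


@dataclass(frozen=True)
class StageFlow:
    x_start: float
    x_end: float
    velocity: float
    direction_deg: float = 0.0


def compose_flow(stages: Sequence[StageConfig], height: float) -> list[StageFlow]:
    """Piecewise-uniform background flow with flux conservation at junctions.

    The first stage's ``axial_flow`` sets the inlet flux; a realignment stage
    adds its side-inlet flux; every downstream velocity follows from mass
    conservation over the local width.  In the realignment stage, the merged
    direction is the momentum-flux-weighted vector sum of main and side
    streams (axial when the side flow satisfies the realignment rule).
    """
    flows = []
    x = 0.0
    flux = None
    for i, st in enumerate(stages):
        if i == 0:
            if st.axial_flow <= 0:
                raise DeviceError("first stage needs a positive axial_flow")
            flux = st.axial_flow * st.width * height
            vel = st.axial_flow
            direction = 0.0
        else:
            prev = stages[i - 1]
            if st.kind == "realignment":
                if st.side_flow > 0 and st.side_inlet_width > 0:
                    q_side = st.side_flow * st.side_inlet_width * height
                    theta = prev.tilt_deg
                    u_prev = flux / (prev.width * height)
                    beta = realignment_side_angle(flux, u_prev, theta,
                                                  q_side, st.side_flow)
                    # momentum-flux-weighted merged direction
                    mx = (flux * u_prev * math.cos(math.radians(theta))
                          + q_side * st.side_flow * math.cos(math.radians(beta)))
                    my = (flux * u_prev * math.sin(math.radians(theta))
                          + q_side * st.side_flow * math.sin(math.radians(beta)))
                    direction = math.degrees(math.atan2(my, mx))
                    flux = flux + q_side
                else:
                    direction = 0.0
            else:
                direction = 0.0
            vel = flux / (st.width * height)
        flows.append(StageFlow(x_start=x, x_end=x + st.length,
                               velocity=vel, direction_deg=direction))
        x += st.length
    return flows


# ---------------------------------------------------------------------------
# Device runner
# ---------------------------------------------------------------------------

def _stage_field(device: DeviceConfig, st: StageConfig,
                 node_y: float) -> Optional[FirstOrderField]:
    p_a = st.pressure_amplitude
    if p_a == 0.0:
        return None
    geom = ChannelGeometry(length=st.length, width=st.width,
                           height=device.height)
    k = 2.0 * math.pi / device.wavelength
    if st.kind == "focusing":
        # conventional standing wave: nodal lines parallel to the flow,
        # phased so one node sits at node_y (the channel center)
        phase = math.pi / 2.0 - k * node_y
        tilt = 0.0
    else:
        phase = math.pi / 2.0 - k * node_y * math.cos(
            math.radians(st.tilt_deg))
        tilt = st.tilt_deg
    return make_tassaw_field(p_a, device.wavelength, tilt, geom,
                             device.fluid, frequency=device.frequency,
                             phase=phase)


@dataclass
class DeviceResult:
    trajectories: dict[str, Trajectory]
    metrics: dict
    stage_flows: list[StageFlow]
    report: dict


def run_device(device: DeviceConfig, mode: str = "overdamped",
               n_save: int = 120, rtol: float = 1e-6) -> DeviceResult:
    """Trace every particle through all stages and report separation metrics.

    Stage fields are rebuilt per stage (conventional SSAW in focusing,
    tilted-angle SSAW in separation); particle lateral positions carry over
    across stage junctions.  A particle making no axial progress for a tenth
    of its stage residence budget is flagged as trapped.
    """
    flows = compose_flow(device.stages, device.height)
    widths = [st.width for st in device.stages]
    max_width = max(widths)
    # stage channels share the centerline of the widest (final) stage
    centers = [max_width / 2.0 for _ in device.stages]

    offsets = device.release_offsets or (0.0,)
    trajectories: dict[str, Trajectory] = {}
    per_particle_y = {}
    trapped = []
    z = device.trace_height

    for pi, particle in enumerate(device.particles):
        off = offsets[pi % len(offsets)]
        y = centers[0] + off
        x_global = 0.0
        times_all, pos_all, vel_all, fr_all, fd_all = [], [], [], [], []
        t_offset = 0.0
        for si, (st, fl) in enumerate(zip(device.stages, flows)):
            # field phases are set in stage-local coordinates (node on the
            # stage centerline)
            field1 = _stage_field(device, st, node_y=st.width / 2.0)
            y_lo = centers[si] - st.width / 2.0
            geom_flow = fl.velocity
            duration = 1.25 * st.length / geom_flow
            vdir = np.array([math.cos(math.radians(fl.direction_deg)),
                             math.sin(math.radians(fl.direction_deg)), 0.0])
            bg = (lambda v=geom_flow, d=vdir: (lambda pos: v * d))()
            y_local = y - y_lo
            y_local = min(max(y_local, particle.radius),
                          st.width - particle.radius)
            # x-exit only; the sidewalls are solid (particles slide along them)
            domain = ((-1e-6, st.length), (-st.width, 2.0 * st.width))
            trs = trace([particle], field1, device.fluid, duration,
                        background_flow=bg,
                        release_positions=[np.array([0.0, y_local, z])],
                        mode=mode, z_plane=z, n_save=n_save, rtol=rtol,
                        domain=domain, walls_y=(0.0, st.width))
            tr = trs[0]
            if tr.positions[-1, 0] < 0.98 * st.length:
                trapped.append((particle.label, st.kind))
            times_all.append(tr.times + t_offset)
            pos = tr.positions.copy()
            pos[:, 0] += x_global
            pos[:, 1] += y_lo
            pos_all.append(pos)
            vel_all.append(tr.velocities)
            fr_all.append(tr.f_rad)
            fd_all.append(tr.f_drag)
            t_offset += tr.times[-1] + 1e-12
            x_global += st.length
            y = tr.positions[-1, 1] + y_lo
        times = np.concatenate(times_all)
        keep = np.concatenate([[True], np.diff(times) > 0])
        traj = Trajectory(particle=particle, times=times[keep],
                          positions=np.vstack(pos_all)[keep],
                          velocities=np.vstack(vel_all)[keep],
                          f_rad=np.vstack(fr_all)[keep],
                          f_drag=np.vstack(fd_all)[keep])
        trajectories[particle.label] = traj
        per_particle_y[particle.label] = y

    outlet_x = sum(st.length for st in device.stages) * 0.999999
    metrics = separation_metrics(list(trajectories.values()), outlet_x)
    sep_start_y = {lab: tr.positions[0, 1]
                   for lab, tr in trajectories.items()}
    lateral = {}
    for lab, tr in trajectories.items():
        sep_x0 = sum(st.length for st in device.stages[:-1])
        idx = np.searchsorted(tr.positions[:, 0], sep_x0)
        idx = min(idx, len(tr.positions) - 1)
        lateral[lab] = abs(per_particle_y[lab] - tr.positions[idx, 1])
    report = {
        "device": device.name,
        "seed": device.seed,
        "stage_pressure_amplitudes": {
            f"{st.kind}[{i}]": st.pressure_amplitude
            for i, st in enumerate(device.stages)},
        "stage_flows": [{"velocity": f.velocity,
                         "direction_deg": f.direction_deg} for f in flows],
        "separation_stage_lateral_displacement": lateral,
        "trapped": trapped,
    }
    return DeviceResult(trajectories=trajectories, metrics=metrics,
                        stage_flows=flows, report=report)


def sweep_tilt_angle(device: DeviceConfig, thetas: Sequence[float],
                     voltages: Sequence[float],
                     mode: str = "overdamped", n_save: int = 60,
                     rtol: float = 1e-5) -> pd.DataFrame:
    """Grid sweep over separation-stage tilt and drive voltage.

    Returns a tidy frame (theta_deg, voltage, max_pairwise_distance) ranked
    by the separation metric, one row per grid point; deterministic for a
    fixed device seed.
    """
    rows = []
    for theta in thetas:
        if not 0.0 < theta < 90.0:
            raise DeviceError("tilt angles must lie in (0, 90) degrees")
        for volts in voltages:
            stages = list(device.stages)
            sep = stages[-1]
            if sep.kind != "separation":
                raise DeviceError("last stage must be the separation stage")
            stages[-1] = replace(sep, tilt_deg=float(theta),
                                 drive_voltage=float(volts))
            dev = replace(device, stages=tuple(stages))
            res = run_device(dev, mode=mode, n_save=n_save, rtol=rtol)
            rows.append({"theta_deg": float(theta), "voltage": float(volts),
                         "max_pairwise_distance":
                             res.metrics["max_pairwise_distance"]})
    frame = pd.DataFrame(rows)
    return frame.sort_values("max_pairwise_distance", ascending=False,
                             ignore_index=True)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _preset_path(name: str):
    return resources.files("tassaw").joinpath("presets", f"{name}.yaml")


def load_preset(name: str, particle_set: Optional[str] = None) -> DeviceConfig:
    """Load a shipped device preset (``validation_tassaw``/``sheathless_tassaw``).

    ``particle_set`` picks among the preset's particle groups (e.g. ``beads``
    or ``cells`` for the sheathless device).
    """
    ref = _preset_path(name)
    if not ref.is_file():
        avail = [p.name[:-5] for p in resources.files("tassaw")
                 .joinpath("presets").iterdir() if p.name.endswith(".yaml")]
        raise DeviceError(f"unknown preset {name!r}; available: {avail}")
    with ref.open("r") as fh:
        raw = yaml.safe_load(fh)
    return device_from_dict(raw, particle_set=particle_set)


def device_from_dict(raw: dict, particle_set: Optional[str] = None) -> DeviceConfig:
    fluid = load_material(raw["fluid"])
    groups = raw["particle_sets"]
    key = particle_set or raw.get("default_particle_set") or next(iter(groups))
    if key not in groups:
        raise DeviceError(f"unknown particle set {key!r}; "
                          f"available: {sorted(groups)}")
    particles = []
    for p in groups[key]:
        mat = load_material(p["material"])
        particles.append(ParticleSpec.from_material(
            mat, diameter=float(p["diameter_m"]), label=p.get("name")))
    stages = []
    for s in raw["stages"]:
        cal = None
        if "calibration" in s:
            cal = Calibration(voltage=float(s["calibration"]["voltage_v"]),
                              pressure=float(s["calibration"]["pressure_pa"]))
        voltage_key = f"drive_voltage_v_{key}"
        volts = float(s.get(voltage_key, s.get("drive_voltage_v", 0.0)))
        stages.append(StageConfig(
            kind=s["kind"], length=float(s["length_m"]),
            width=float(s["width_m"]), tilt_deg=float(s.get("tilt_deg", 0.0)),
            drive_voltage=volts, calibration=cal,
            axial_flow=float(s.get("axial_flow_m_s", 0.0)),
            side_flow=float(s.get("side_flow_m_s", 0.0)),
            side_inlet_width=float(s.get("side_inlet_width_m", 0.0))))
    return DeviceConfig(
        stages=tuple(stages), height=float(raw["channel_height_m"]),
        fluid=fluid, particles=tuple(particles),
        frequency=float(raw["frequency_hz"]),
        wavelength=float(raw["wavelength_m"]), name=raw.get("name", "device"),
        release_offsets=tuple(float(v) for v in raw.get(
            "release_offsets_m", [0.0])),
        trace_height=float(raw.get("trace_height_m", 20e-6)),
        seed=int(raw.get("seed", 0)))
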