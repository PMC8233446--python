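"""Lagrangian particle tracing under radiation force, drag and background flow.

Two integration modes:

- ``overdamped`` (default): the particle relaxes to its terminal velocity
  instantly, ``v_p = v_fluid + F_rad / (6 pi eta r)``; only positions are
  integrated.
- ``inertial``: integrates ``m dv/dt = F_drag + F_rad`` (buoyancy/gravity are
  excluded from the in-plane balance).

The vertical coordinate is held fixed by default (vertical radiation force
assumed balanced by vertical drag in shallow channels); full 3D motion is
optional.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from tassaw.field import FirstOrderField
from tassaw.forces import ParticleSpec, radiation_force, stokes_drag
from tassaw.materials import MaterialRecord
from tassaw.streaming import SecondOrderField


class TracingError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Time series of one particle's motion with the force decomposition."""

    particle: ParticleSpec
    times: np.ndarray            # (n,)
    positions: np.ndarray        # (n, 3)
    velocities: np.ndarray       # (n, 3)
    f_rad: np.ndarray            # (n, 3)
    f_drag: np.ndarray           # (n, 3)
    exited: bool = False
    exit_time: Optional[float] = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise TracingError("trajectory times must be strictly increasing")
        if not (np.all(np.isfinite(self.positions))
                and np.all(np.isfinite(self.velocities))):
            raise TracingError("non-finite trajectory values")

    @property
    def final_position(self) -> np.ndarray:
        return self.positions[-1]

    def lateral_displacement(self) -> float:
        """Net |y(final) - y(initial)|."""
        return float(abs(self.positions[-1, 1] - self.positions[0, 1]))


def _streaming_sampler(streaming: Optional[SecondOrderField]):
    if streaming is None:
        return lambda pos: np.zeros(3)
    from scipy.interpolate import RegularGridInterpolator
    xc, yc, zc = streaming.cell_centers()
    vc = streaming.velocity_at_centers()
    interps = [RegularGridInterpolator((xc, yc, zc), vc[..., i],
                                       bounds_error=False, fill_value=0.0)
               for i in range(3)]
    lx = streaming.lengths[0]

    def sample(pos):
        q = np.array([pos[0] % lx, pos[1], pos[2]])
        return np.array([float(it(q)) for it in interps])

    return sample


def trace(particles: Sequence[ParticleSpec], field1: Optional[FirstOrderField],
          fluid: MaterialRecord, duration: float,
          streaming: Optional[SecondOrderField] = None,
          background_flow: Optional[Callable] = None,
          release_positions: Optional[Sequence] = None,
          mode: str = "overdamped", z_plane: float = 20e-6,
          hold_z: bool = True, n_save: int = 200,
          rtol: float = 1e-7, atol: float = 1e-12,
          domain: Optional[tuple] = None,
          walls_y: Optional[tuple] = None) -> list[Trajectory]:
    """Integrate particle motion for ``duration`` seconds.

    ``background_flow`` maps position -> velocity 3-vector (defaults to rest).
    ``release_positions`` is one 3-vector per particle (default: channel
    center at height ``z_plane``).  A particle leaving ``domain``
    (an ``((xlo, xhi), (ylo, yhi))`` pair, default the field footprint)
    terminates its trajectory with the exit flag set.  ``walls_y`` instead
    treats the given (ylo, yhi) pair as solid sidewalls along which particles
    slide (the outward velocity component is suppressed within one particle
    radius of the wall), mirroring near-wall accumulation.
    """
    if duration <= 0:
        raise TracingError("duration must be positive")
    if mode not in ("overdamped", "inertial"):
        raise TracingError(f"unknown mode {mode!r}")
    eta = fluid.dynamic_viscosity
    if eta is None:
        raise TracingError("fluid needs a dynamic viscosity")

    if domain is None and field1 is not None:
        geom = field1.geometry
        domain = ((0.0, geom.length), (0.0, geom.width))
    bg = background_flow or (lambda pos: np.zeros(3))
    v2 = _streaming_sampler(streaming)

    if release_positions is None:
        if field1 is None:
            raise TracingError("need release positions without a field")
        geom = field1.geometry
        release_positions = [np.array([0.0, geom.width / 2.0, z_plane])
                             for _ in particles]

    def f_rad(particle, pos):
        if field1 is None:
            return np.zeros(3)
        return radiation_force(field1, particle,
                               (pos[0], pos[1], pos[2]), fluid,
                               check_bounds=False)

    out: list[Trajectory] = []
    for particle, pos0 in zip(particles, release_positions):
        pos0 = np.asarray(pos0, dtype=float)
        mobility = 1.0 / (6.0 * math.pi * eta * particle.radius)

        def fluid_velocity(pos):
            return bg(pos) + v2(pos)

        def wall_clamp(pos, vel_y):
            if walls_y is None:
                return vel_y
            ylo, yhi = walls_y
            r = particle.radius
            if pos[1] <= ylo + r and vel_y < 0.0:
                return 0.0
            if pos[1] >= yhi - r and vel_y > 0.0:
                return 0.0
            return vel_y

        if mode == "overdamped":
            def rhs(t, yv):
                pos = np.array([yv[0], yv[1], pos0[2] if hold_z else yv[2]])
                vel = fluid_velocity(pos) + mobility * f_rad(particle, pos)
                vel = np.array([vel[0], wall_clamp(pos, vel[1]),
                                0.0 if hold_z else vel[2]])
                return vel

            y0 = pos0.copy()
        else:
            def rhs(t, yv):
                pos = np.array([yv[0], yv[1], pos0[2] if hold_z else yv[2]])
                vel = yv[3:6]
                drag = stokes_drag(fluid_velocity(pos), vel,
                                   particle.radius, eta)
                acc = (drag + f_rad(particle, pos)) / particle.mass
                dpos = vel.copy()
                dpos[1] = wall_clamp(pos, dpos[1])
                if dpos[1] == 0.0 and vel[1] * acc[1] > 0.0:
                    acc[1] = 0.0
                if hold_z:
                    dpos[2] = 0.0
                    acc[2] = 0.0
                return np.concatenate([dpos, acc])

            y0 = np.concatenate([pos0, fluid_velocity(pos0)])

        events = []
        if domain is not None:
            (xlo, xhi), (ylo, yhi) = domain

            def exit_event(t, yv):
                return min(yv[0] - xlo, xhi - yv[0], yv[1] - ylo, yhi - yv[1])

            exit_event.terminal = True
            exit_event.direction = -1
            events.append(exit_event)

        t_eval = np.linspace(0.0, duration, n_save)
        method = "LSODA" if mode == "inertial" else "RK45"
        sol = solve_ivp(rhs, (0.0, duration), y0, method=method,
                        t_eval=t_eval, events=events or None,
                        rtol=rtol, atol=atol, max_step=duration / 20.0)
        if sol.status == -1:
            raise TracingError(f"integration failed: {sol.message}")
        times = sol.t
        states = sol.y.T
        exited = sol.status == 1
        exit_time = None
        if exited and sol.t_events and len(sol.t_events[0]):
            exit_time = float(sol.t_events[0][0])
            if sol.y_events[0].size:
                times = np.append(times, sol.t_events[0][:1])
                states = np.vstack([states, sol.y_events[0][:1]])
        # guard against duplicated final sample
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, states = times[keep], states[keep]

        positions = states[:, :3].copy()
        if hold_z:
            positions[:, 2] = pos0[2]
        if mode == "inertial":
            velocities = states[:, 3:6]
        else:
            velocities = np.array([rhs(t, s) for t, s in zip(times, states)])
        fr = np.array([f_rad(particle, p) for p in positions])
        fd = np.array([stokes_drag(fluid_velocity(p), v, particle.radius, eta)
                       for p, v in zip(positions, velocities)])
        out.append(Trajectory(particle=particle, times=times,
                              positions=positions, velocities=velocities,
                              f_rad=fr, f_drag=fd, exited=exited,
                              exit_time=exit_time))
    return out


# ---------------------------------------------------------------------------
# Separation metrics
# ---------------------------------------------------------------------------

def separation_metrics(trajectories: Sequence[Trajectory],
                       outlet_x: float) -> dict:
    """Lateral positions where each trajectory crosses ``outlet_x``.

    Reports per-particle outlet y (NaN when the trajectory never reaches the
    outlet) and the maximum pairwise inter-particle distance delta among the
    crossing particles.
    """
    outlet_y = {}
    for n_traj, traj in enumerate(trajectories):
        xs = traj.positions[:, 0]
        ys = traj.positions[:, 1]
        idx = np.nonzero(xs >= outlet_x)[0]
        label = traj.particle.label
        if label in outlet_y:  # disambiguate duplicate labels
            label = f"{label}#{n_traj}"
        if len(idx) == 0:
            outlet_y[label] = math.nan
            continue
        i = idx[0]
        if i == 0 or xs[i] == xs[i - 1]:
            outlet_y[label] = float(ys[i])
        else:
            frac = (outlet_x - xs[i - 1]) / (xs[i] - xs[i - 1])
            outlet_y[label] = float(ys[i - 1] + frac * (ys[i] - ys[i - 1]))
    vals = [v for v in outlet_y.values() if not math.isnan(v)]
    delta = max((abs(a - b) for i, a in enumerate(vals) for b in vals[i + 1:]),
                default=0.0)
    return {"outlet_x": outlet_x, "outlet_y": outlet_y,
            "max_pairwise_distance": float(delta),
            "n_crossed": len(vals), "n_total": len(list(trajectories))}
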