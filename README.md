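# tassaw

Device-level simulator for particle and cell separation in (tilted-angle)
standing-surface-acoustic-wave — SSAW/taSSAW — microfluidics, built on the
boundary-driven acoustic-streaming methodology with a limiting-velocity slip
condition:

- **materials** — SI material library (water, polystyrene, PDMS, 128° YX
  LiNbO₃, WBC, MCF-7), derived acoustic quantities (compressibility, contrast
  factor, viscous boundary-layer thickness), Bond-matrix rotation of
  piezoelectric tensor sets to arbitrary crystallographic cuts, and
  voltage ↔ dBm drive-power conversion.
- **substrate** — free-surface Rayleigh-SAW solver on a rotated piezoelectric
  half-space via the quasi-static partial-wave (Stroh) formalism: phase
  velocity, depth profiles, energy confinement and polarization diagnostics.
- **field** — semi-analytic first-order (ta)SSAW pressure/velocity fields
  with nodal/antinodal line loci.
- **streaming** — limiting-velocity slip on the vibrating bottom interface
  and the second-order creeping (Stokes) flow it drives, on a staggered MAC
  grid (periodic ends, no-slip walls, sparse direct solve).
- **forces** — acoustic radiation force with viscous scattering corrections
  (monopole/dipole coefficients) and Stokes drag.
- **tracing** — Lagrangian particle tracing (overdamped or inertial),
  separation metrics at the outlet.
- **device** — multi-stage devices (focusing → realignment → separation),
  per-stage drive calibration, shipped presets for a validation separator
  (19.32 MHz, θ=15°, 9.9/7.3 µm beads) and a sheathless three-stage separator
  (9.63 MHz, θ=10°, 4/10 µm beads or WBC/MCF-7 cells), and tilt-angle ×
  voltage optimization sweeps.

## CLI

```sh
tassaw materials list
tassaw materials show water
tassaw saw solve --cut-angle 128 --wavelength 400e-6   # v_R, energy fraction, ellipse
tassaw field render --tilt 10 --out field.vtk          # VTK slice of p1/v1
tassaw streaming slip --csv slip.csv                   # |u_L| along the center-line
tassaw force probe --diameter 10e-6 --csv force.csv
tassaw device run sheathless_tassaw --out out/         # preset name or YAML path
tassaw device run sheathless_tassaw --particle-set cells
tassaw device sweep sheathless_tassaw --theta 5:45:5 --volts 20,30,40
```

Exit codes: 0 ok, 1 configuration error, 2 runtime error. Outputs are tidy
CSV trajectories, legacy-ASCII VTK structured grids, and a JSON summary
carrying the seed and software version. Run configs are YAML with explicit
SI unit suffixes (see `src/tassaw/presets/*.yaml`); unknown keys are hard
errors.

## Conventions

Right-handed coordinates with x the flow axis, z the channel height from the
substrate; the standing wave propagates across the nodal lines along
`x_r = x sinθ + y cosθ`, so θ is the tilt of the nodal lines from the flow
axis. Quantities are SI throughout; drive power follows P ∝ V² per-device
calibrations.
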