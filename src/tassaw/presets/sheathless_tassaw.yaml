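# Three-stage sheathless separator preset (focusing -> realignment ->
# separation).  Printed operating point: lambda = 400 um (9.63 MHz drive),
# tilt 10 deg, inlet flow 6 mm/s, side flow 18 mm/s, focusing width
# lambda/2; separation-stage amplitude calibration 40 V -> 1 MPa and
# focusing-stage calibration 10 V -> 0.5 MPa.  Stage lengths, the side-inlet
# width and release offsets are NOT printed for this device; the defaults
# below are chosen so each stage's residence time exceeds its
# focusing/realignment time at the preset flows.  Override freely.
name: sheathless_tassaw
fluid: water
frequency_hz: 9.63e+6
wavelength_m: 400.0e-6
channel_height_m: 75.0e-6
trace_height_m: 20.0e-6
seed: 0
default_particle_set: beads
particle_sets:
  beads:
    - {name: ps_4um, material: polystyrene, diameter_m: 4.0e-6}
    - {name: ps_10um, material: polystyrene, diameter_m: 10.0e-6}
  cells:
    - {name: wbc, material: wbc, diameter_m: 12.0e-6}
    - {name: mcf7, material: mcf7, diameter_m: 20.0e-6}
release_offsets_m: [-50.0e-6, 50.0e-6]
stages:
  - kind: focusing
    length_m: 3.0e-3
    width_m: 200.0e-6
    axial_flow_m_s: 6.0e-3
    drive_voltage_v: 10.0
    drive_voltage_v_cells: 5.0
    calibration: {voltage_v: 10.0, pressure_pa: 0.5e+6}
  - kind: realignment
    length_m: 1.0e-3
    width_m: 1.0e-3
    side_flow_m_s: 18.0e-3
    side_inlet_width_m: 400.0e-6
  - kind: separation
    length_m: 4.0e-3
    width_m: 1.0e-3
    tilt_deg: 10.0
    drive_voltage_v: 40.0
    drive_voltage_v_cells: 30.0
    calibration: {voltage_v: 40.0, pressure_pa: 1.0e+6}
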