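# Validation-device preset: single tilted-angle separation stage.
# Printed operating point: 19.32 MHz (lambda = 200 um), tilt 15 deg,
# channel w = 1000 um, h = 75 um, polystyrene beads of 9.9 and 7.3 um,
# 7.5 V drive calibrated to a 1 MPa peak first-order pressure.
# The inlet flow velocity is NOT printed for this device; the 6 mm/s
# default is borrowed from the sheathless preset -- override as needed.
name: validation_tassaw
fluid: water
frequency_hz: 19.32e+6
wavelength_m: 200.0e-6
channel_height_m: 75.0e-6
trace_height_m: 20.0e-6
seed: 0
default_particle_set: beads
particle_sets:
  beads:
    - {name: ps_9.9um, material: polystyrene, diameter_m: 9.9e-6}
    - {name: ps_7.3um, material: polystyrene, diameter_m: 7.3e-6}
release_offsets_m: [0.0]
stages:
  - kind: separation
    length_m: 4.0e-3
    width_m: 1.0e-3
    tilt_deg: 15.0
    axial_flow_m_s: 6.0e-3
    drive_voltage_v: 7.5
    calibration: {voltage_v: 7.5, pressure_pa: 1.0e+6}
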