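# Built-in material library (SI units, properties at 25 degC unless noted).
# Stored compressibilities take precedence over values recomputed from
# density/sound speed; see tassaw.materials.consistency_report.
water:
  kind: fluid
  density_kg_m3: 997.0
  sound_speed_m_s: 1497.0
  dynamic_viscosity_pa_s: 0.890e-3
  bulk_viscosity_pa_s: 2.47e-3
  compressibility_per_pa: 4.48e-10

polystyrene:
  kind: particle
  density_kg_m3: 1050.0
  sound_speed_m_s: 2350.0
  poisson_ratio: 0.35
  compressibility_per_pa: 1.72e-10

pdms:
  kind: wall
  density_kg_m3: 920.0
  sound_speed_m_s: 1076.5
  attenuation_db_cm: 47.85

linbo3_128yx:
  kind: substrate
  density_kg_m3: 4650.0
  sound_speed_m_s: 3997.0

wbc:
  kind: cell
  density_kg_m3: 1019.0
  compressibility_per_pa: 3.99e-10
  diameter_m: 12.0e-6

mcf7:
  kind: cell
  density_kg_m3: 1068.0
  compressibility_per_pa: 4.22e-10
  diameter_m: 20.0e-6
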