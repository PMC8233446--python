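# Single-crystal lithium niobate constants, trigonal class 3m, stress-charge
# form, crystal (XYZ) frame.  Values follow the widely used set of Warner,
# Onoe & Coquin, J. Acoust. Soc. Am. 42, 1223 (1967): stiffness at constant
# electric field (Pa), piezoelectric stress constants (C/m^2), and relative
# permittivity at constant strain.
density_kg_m3: 4650.0
stiffness_pa:
  c11: 2.03e+11
  c12: 0.53e+11
  c13: 0.75e+11
  c14: 0.09e+11
  c33: 2.45e+11
  c44: 0.60e+11
piezo_c_m2:
  e15: 3.70
  e22: 2.50
  e31: 0.20
  e33: 1.30
relative_permittivity_strain:
  eps11: 44.0
  eps33: 29.0
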