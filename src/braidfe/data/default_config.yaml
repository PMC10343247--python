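# Default study configuration: Kevlar-reinforced PCU braided meniscus.
# Moduli in GPa at this boundary; the package works in N-mm-MPa internally.
materials:
  fiber:                      # Kevlar yarn (transversely isotropic)
    longitudinal_modulus_gpa: 128.7
    transverse_modulus_gpa: 12.87
    longitudinal_poisson_ratio: 0.3
    longitudinal_shear_modulus_gpa: 12.87
    transverse_shear_modulus_gpa: 12.87
  matrix:                     # polycarbonate polyurethane (PCU)
    elastic_modulus_gpa: 0.057
    poisson_ratio: 0.43
bridging:
  Vf: 0.70                    # back-solved from the bundle axial modulus
  alpha: 0.30                 # axial-shear bridging parameter
  beta: 0.30                  # transverse-modulus bridging parameter
geometry:
  length_mm: 32.0
  width_mm: 26.0
  height_mm: 11.0
  n_layers: 5
  level_of_layer: [1, 1, 2, 2, 3]
  transverse_counts: [6, 4, 2]
  longitudinal_counts: [13, 12, 8]
  transverse_lengths_mm: [45.0, 40.0, 35.0]
  longitudinal_shortening_mm: [0.0, 8.0, 6.0]
  fiber_width_mm: 2.0
  fiber_height_mm: 1.0
  gap_mm: 2.0
  fan_angle_deg: 15.0
  inner_thickness_mm: 3.0
  inner_apex_fraction: 0.3846153846153846
  interlock_diameter_mm: 0.5
mesh:
  macro_resolution_mm: 1.5
  rvc_divisions: 5
  overlap_correction: true
loads:
  newtons: [400.0, 600.0, 800.0, 1200.0, 1400.0]
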