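# Default configuration for the sagittal-plane knee model.

# The sweep factors, analysis window, anthropometrics, strain limit,
# friction coefficient and integrator settings define the standard
# experiment protocol; geometry, stiffness and PCSA values are
# literature-typical calibration defaults (see docs/methods.md).

seed: 0
output_dir: results

gait:
  n_samples: 100
  body_mass: 70.0          # kg
  stance_knee_peak: 18.0   # deg
  swing_knee_peak: 64.0    # deg
  knee_min: 3.0            # deg
  toe_off_fraction: 0.60   # cycle fraction
  noise_sd: 0.5            # deg
  seed: 0

geometry:
  condyle_radius: 25.0     # mm
  dish_radius: 35.0        # mm
  dish_rim_slope: 0.095    # dimensionless
  plateau_slope: 0.0       # deg
  thigh_length: 420.0      # mm
  sites: {}                # optional per-site [x, y] overrides (mm)

body:
  body_mass: 70.0          # kg
  height: 1.72             # m
  shank_mass_fraction: 0.0465
  foot_mass_fraction: 0.0145
  shank_length_fraction: 0.246
  thigh_length_fraction: 0.245
  shank_com_fraction: 0.433
  shank_gyration_fraction: 0.302
  foot_com_offset: 0.05    # m
  gravity: 9.81            # m/s^2

ligaments:
  strain_limit: 0.03
  toe_transition: at_limit # at_limit | double_limit
  stiffness: {}            # per-ligament N/strain overrides
  reference_strain: {}     # per-bundle neutral-state strain offsets

muscles:
  pcsa: {}                 # per-muscle mm^2 overrides

contact:
  friction_mu: 0.01
  restitution: 0.0         # fixed: inelastic
  contact_stiffness: 40000.0  # N/mm
  contact_damping_ratio: 1.0
  slip_velocity: 1.0       # mm/s
  tissue_damping: 0.8      # N s/mm

integrator:
  dt: 0.02                 # s
  n_cycles: 2
  tolerance_translation: 0.01  # mm
  tolerance_rotation: 0.1      # deg

sweep:
  pcl_factors: [1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.15]
  hamstring_factors: [1.0, 0.9, 0.8, 0.7, 0.6]
  pcl_residual: 0.15
  window: [0.76, 1.0]
  trend_degree: 2
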