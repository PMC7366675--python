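mesh:
  layers:
  - name: scalp
    outer_radius_mm: 92.0
    conductivity_S_per_m: 0.465
  - name: skull
    outer_radius_mm: 86.0
    conductivity_S_per_m: 0.01
  - name: csf
    outer_radius_mm: 80.0
    conductivity_S_per_m: 1.654
  - name: gray
    outer_radius_mm: 78.0
    conductivity_S_per_m: 0.276
  - name: white
    outer_radius_mm: 70.0
    conductivity_S_per_m: 0.126
  edge_length_mm: 10.0
  seed: 0
electrodes:
  n_candidates: 16
  diameter_mm: 10.0
  thickness_mm: 2.5
  reference_polar_angle_deg: 115.0
roi:
  target_center_mm:
  - 0.0
  - 0.0
  - 37.0
  target_radius_mm: 6.0
stimulation:
  f1_hz: 2000.0
  f2_hz: 2010.0
  alpha_min_mA: 0.5
  alpha_max_mA: 1.5
  alpha_step_mA: 0.05
  total_current_mA: 2.0
  constraint_threshold_V_per_m: 0.2
  objective_mode: max_pr_with_amplitude_floor
  pr_floor: 1.0
  homogeneous_sigma_S_per_m: 0.276
output:
  directory: runs/demo16
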