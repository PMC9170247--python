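# Packaged default parameters. All rates are per model time unit,
# concentrations in arbitrary units. One section per GRN model.
induction:
  beta_L: 10.0
  gamma_L: 1.0
  gamma_S: 1.0
  k_trans_act: 1.0
  K_act: 0.5
  h_act: 2.0
inhibition:
  beta_L: 10.0
  beta_R: 10.0
  gamma_L: 1.0
  gamma_R: 1.0
  gamma_S: 1.0
  k_trans_act: 1.0
  K_R_act: 1.0
  K_L_rep: 1.0
  h: 2.0
cistrans:
  beta_N: 10.0
  beta_L: 10.0
  gamma: 1.0
  gamma_S: 1.0
  K_cis: 1.0
  K_trans: 1.0
  K_S: 1.0
  h: 1.0
lattice:
  n_cells: 30
  boundary: periodic
simulate:
  epsilon: 0.01
  t_end: 500.0
  n_frames: 200
phase_diagram:
  k_min: 0.01
  k_max: 100.0
  n_grid: 21
segmentation:
  sigma: 3.0
  global_factor: 1.5
  local_kernel_diameter: 120
  dilate_fill: 5
  erode_fill: 9
  min_area: 3500
  boundary_dilate: 8
  neighborhood_dilate: 25
score:
  pseudocount: 1.0
  display_scale: 1.0e-3
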