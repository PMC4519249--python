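# Full three-layer configuration for a dose sweep of the genetic switch.
# Traffic parameters are the main study condition (reduced round count for an
# interactive-scale scan); RNA and protein constants are the documented
# placeholder defaults.
seed: 3
ti:
  pX: {tau_B: 20.0, tau_I: 12.0, noise_cv: 0.05}
  pY: {tau_B: 20.0, tau_I: 9.5, noise_cv: 0.05}
  L: 400
  v_mean: 50.0
  v_sd: 2.5
  sdc_survival: 0.1
  collision_one_survives: 0.8
  n_rounds: 4000
  seed: 3
kinetics:
  k_bxy: 0.0017
  k_bxky: 0.0017
  k_bxyh: 0.0017
  k_bxkyh: 0.0017
  k_uxy: 0.001
  k_uxkyh: 0.01
  lambda_x: 0.003
  lambda_y: 0.003
  lambda_xk: 0.003
  lambda_yh: 0.003
  lambda_xy: 0.003
  lambda_xky: 0.003
  lambda_xyh: 0.003
  lambda_xkyh: 0.003
  mu: 0.0003
gn:
  k_X: 1.4
  k_Y: 0.01
  k_YZ: 0.002
  k_XZ: 0.01
  k_uXZ: 0.001
  K_OY: 10.0
  f_Y_min: 0.0185
  f_Y_max: 0.087
  lambda_X: 0.003
  lambda_Y: 0.0003
  lambda_Z: 0.003
  lambda_XZ: 0.0003
  mu: 0.0003
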