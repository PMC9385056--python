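label: obese
units:
  time: hours
  drug_amount: mg
  concentration: mg/L
  cox1: arbitrary units (percent of total where stated)
pk:
  ka: 6.0
  k1: 2.0
  k2: 4.0
  k3: 12.0
  k4: 0.5
  kd_T: 1.0
  kd_B: 2.5366
  kd_S: 1.0
  k_he: 0.6
  F: 0.2             # reduced systemic bioavailability (severe obesity)
  V_B: 5.0
  V_T: 1.08738
  V_S: 0.75
pd:
  phi_max: 0.23162
  K_a50: 1.50297
  h: 3.12405
  w_portal: 0.14914
unit:
  tau: 0.0
  T_mat: 162.0
  T_burst: 24.0
  L_MK: 168.0
  t_half_P: 120.0
  T_apop: 48.0
  N_P: 3000.0
  p_ss: 1.0
  p_burst: 2.0
  kd_x_ss: 0.00825
  k5_ss: 0.2
  k5_shape: 3.0
population:
  n_units: 5000
  platelet_count: 250000.0
  dt_target: 0.25
  pre_window: 120.0
  recovery_margin: 72.0
  pk_dt: 0.01
notes:
  provenance: >-
    Severe obesity: identical biology to the healthy scenario; only the
    systemic bioavailability F differs (increased pre-systemic hydrolysis).
    An optional body-weight scaling of V_B is deliberately not applied by
    default.
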