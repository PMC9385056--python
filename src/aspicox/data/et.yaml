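label: ET
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
  F: 1.0
  V_B: 5.0
  V_T: 1.08738
  V_S: 0.75
pd:
  phi_max: 0.324268  # healthy value x1.4, proportional to the platelet count
  K_a50: 1.50297
  h: 3.12405
  w_portal: 0.14914
unit:
  tau: 0.0
  T_mat: 78.0        # MK stage compressed to half: accelerated megakaryopoiesis
  T_burst: 12.0
  L_MK: 84.0         # decreased MK lifetime
  t_half_P: 36.0     # shortened platelet survival (accelerated turnover)
  T_apop: 48.0
  N_P: 3000.0
  p_ss: 1.4          # increased COX-1 expression in MKs (x1.4, tracking platelet count)
  p_burst: 2.8
  kd_x_ss: 0.00825
  k5_ss: 0.2
  k5_shape: 3.0
population:
  n_units: 5000
  platelet_count: 350000.0   # thrombocytosis under cytoreduction; scales the acetylation flux x1.4
  dt_target: 0.25
  pre_window: 120.0
  recovery_margin: 72.0
  pk_dt: 0.01
notes:
  provenance: >-
    Essential thrombocythemia (accelerated platelet turnover): differs from
    the healthy scenario in the MK-stage durations (halved lifetime), MK
    COX-1 production and the maximal acetylation flux (both increased in
    proportion to the platelet count), the platelet count itself, and a
    shortened platelet half-life.  Magnitudes are this package's calibration
    of the reported ET phenotype.
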