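label: healthy
units:
  time: hours
  drug_amount: mg
  concentration: mg/L
  cox1: arbitrary units (percent of total where stated)
pk:
  ka: 6.0          # GI absorption [1/h]
  k1: 2.0          # systemic blood -> tissue [1/h]
  k2: 4.0          # tissue -> systemic blood [1/h]
  k3: 12.0         # portal -> systemic transfer [1/h]
  k4: 0.5          # systemic -> portal backflow [1/h]
  kd_T: 1.0        # hydrolysis in tissue [1/h]
  kd_B: 2.5366     # hydrolysis in systemic blood [1/h]; sets the 20-min terminal half-life
  kd_S: 1.0        # hydrolysis in portal blood [1/h]
  k_he: 0.6        # hepatic extraction fraction [-]
  F: 1.0           # systemic bioavailability [-]
  V_B: 5.0         # systemic blood volume [L]
  V_T: 1.08738     # effective tissue (marrow) distribution volume [L]
  V_S: 0.75        # portal blood volume [L]
pd:
  phi_max: 0.23162 # maximal fractional acetylation rate [1/h]
  K_a50: 1.50297   # half-maximal aspirin concentration [mg/L]
  h: 3.12405           # steepness of the empirical concentration sigmoid [-]
  w_portal: 0.14914 # portal-blood share of platelet exposure [-]
unit:
  tau: 0.0
  T_mat: 162.0     # MK maturation [h]; platelet release fills the last 6 h of MK life
  T_burst: 24.0    # transcription burst duration [h]
  L_MK: 168.0      # MK lifetime [h]
  t_half_P: 120.0  # platelet half-life [h] (lifespan = 2x)
  T_apop: 48.0     # apoptotic decline duration [h]
  N_P: 3000.0      # platelets generated per MK [-]
  p_ss: 1.0        # steady-state COX-1 production [au/h]
  p_burst: 2.0     # production during the burst [au/h]
  kd_x_ss: 0.00825 # COX-1 degradation in MKs [1/h]
  k5_ss: 0.2       # MK -> platelet transfer scale [1/h]
  k5_shape: 3.0    # transfer ramp exponent over the release window [-]
population:
  n_units: 5000
  platelet_count: 250000.0   # platelets per uL
  dt_target: 0.25
  pre_window: 120.0
  recovery_margin: 72.0
  pk_dt: 0.01
notes:
  provenance: >-
    Nominal values calibrated by this package so that the simulator
    reproduces the published single-unit endpoint percentages of repeated
    od/bid dosing, the 20-min terminal half-life of systemic aspirin, and
    physiological MK/platelet turnover timescales.
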