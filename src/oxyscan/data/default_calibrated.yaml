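class_models:
- class_name: f_cell
  ei_deoxy: 0.44
  ei_oxy: 0.6
  irreversible_fraction: 0.0
  lysis_fraction: 0.0
  p50_mmHg: 10.0
  slope_mmHg: 5.0
- class_name: non_f_sickle
  ei_deoxy: 0.3675
  ei_oxy: 0.54375
  irreversible_fraction: 0.25
  lysis_fraction: 0.05
  p50_mmHg: 18.3125
  slope_mmHg: 6.0
- class_name: dense
  ei_deoxy: 0.03
  ei_oxy: 0.25875
  irreversible_fraction: 0.85
  lysis_fraction: 0.35
  p50_mmHg: 38.0
  slope_mmHg: 8.0
dense_amplification: 6.875
dense_weight_cap: 0.5
drbc_link:
  amplitude: 4.375
  high: 4.8
  low: 0.0
  noise_sd: 0.70625
  tau: 24.375
fcell_floor_hbf_slope: 0.001875
fcell_link:
  high: 99.2
  log_mid: 2.4367574288995817
  log_scale: 0.75
  low: 24.0
  noise_sd: 8.0
hb_marginal:
  high: 11.4
  loc: 8.942683617370179
  low: 6.9
  sd: 1.2
hbf_marginal:
  high: 50.6
  loc: 21.167567137112133
  low: 5.6
  sd: 11.5
jitter:
  ei_deoxy_sd: 0.06
  ei_oxy_sd: 0.02375
  p50_sd: 7.0
measurement_noise_sd: 0.003
n_patients: 38
po2_noise_sd: 0.3
protection:
  mid: 1.0
  scale: 1.0
rbc_marginal:
  high: 4.5
  loc: 3.229604165832402
  low: 1.7
  sd: 0.7
sampling:
  deox_s: 1300.0
  hz: 1.0
  plateau_s: 100.0
  po2_high_mmHg: 150.0
  po2_low_mmHg: 5.0
  reox_s: 280.0
seed: 0
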