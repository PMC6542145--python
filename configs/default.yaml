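# Full-size simulated cohort: 107 patients, 71 recurrences, planar phantoms.
mode: simulate
seed: 0
out_dir: results/default
b_values: [0, 800, 1500, 2000]
cohort:
  n_patients: 107
  recurrence_fraction: 0.6635514018691588   # 71/107
  sd_fraction: 0.15
  adc_jitter_sd: 0.02
  snr: 50
  noise_model: rician
  grid_shape: [64, 64]
  spacing: [1.5, 1.5]
  diam_mean_cm: 1.81
  diam_sd_cm: 0.83
refine_fit: false
roi_area_bounds_cm2: [1.0, 2.5]
save_maps: false
save_signals: false
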