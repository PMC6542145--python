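# Minimal four-patient run for quick end-to-end checks.
mode: simulate
seed: 0
out_dir: results/smoke
b_values: [0, 800, 1500, 2000]
cohort:
  n_patients: 4
  recurrence_fraction: 0.5
  snr: 50
  noise_model: rician
save_maps: true
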