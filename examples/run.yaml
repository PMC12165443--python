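# Desk-scale end-to-end run: 30 patients, two 60-second sessions each,
# 20-epoch training per vital. Increase n_patients/duration/epochs for
# study-scale runs (200 patients, 180 s, 300 epochs).
cohort:
  n_patients: 30
  seed: 0
signal:
  duration: 60.0
  noise_sd: 0.002
  offcenter_fraction: 0.05
preprocess:
  window_seconds: 10.0
  split_proportions: [0.70, 0.15, 0.15]
regressors:
  sbp: {epochs: 20}
  dbp: {epochs: 20}
  hb: {epochs: 20}
targets: [sbp, dbp, hb]
output_dir: run_output
global_seed: 7
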