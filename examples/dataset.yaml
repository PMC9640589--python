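# Dataset config for `rtwave analyze`.
# Exactly one of input_path / synthetic must be present.
name: example-synthetic
group: wave
synthetic:
  design:
    trials_per_bin: 200
    include_zero: false
  wave:
    sigma0: 200.0
    amplitude: 100.0
    wavelength: 5.0
  seed: 1
# For a real dataset instead:
# input_path: trials.tsv
# column_map: {RT: rt_ms, subj: participant}
filter:
  outlier_k: 1.96               # SD multiple, or null for no trimming
  outlier_scope: global         # global | participant
  drop_errors: false
differential_mode: vs_estimate  # vs_estimate | vs_target
min_count: 5
axis: 0.0
K: 100
smoothing: null                 # null -> one residual unit per arm point
null_model:
  mu: 0.44
  sigma: 0.27
  reps: 10000
  seed: 2
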