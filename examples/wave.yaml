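# Synthetic generator config for `rtwave simulate`.
# design: trial-table layout; wave: SD envelope along the differential axis.
design:
  differential_min: -15
  differential_max: 15
  counts_shape: flat            # flat | bipartite_exponential | bell
  trials_per_bin: 200
  mean_rt_ms: 1000.0
  response_type: free_entry     # free_entry | two_choice
  n_participants: 20
wave:
  sigma0: 200.0                 # baseline RT SD (ms)
  amplitude: 100.0              # wave amplitude of the SD envelope (ms)
  wavelength: 5.0               # period in differential units
  phase: 0.0
  asymmetry_phase_shift: 0.0    # pi -> anti-phase negative control
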