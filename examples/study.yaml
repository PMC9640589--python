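# Study config for `rtwave study`: a list of dataset configs.
# Exactly two group labels enable the pooled-variance t-test on p_hat.
datasets:
  - name: wave-1
    group: wave
    synthetic:
      design: {trials_per_bin: 200, include_zero: false}
      wave: {sigma0: 200.0, amplitude: 100.0, wavelength: 5.0}
  - name: wave-2
    group: wave
    synthetic:
      design: {trials_per_bin: 200, include_zero: false}
      wave: {sigma0: 200.0, amplitude: 100.0, wavelength: 5.0}
  - name: null-1
    group: "null"
    synthetic:
      design: {trials_per_bin: 200, include_zero: false}
      wave: {sigma0: 200.0, amplitude: 0.0}
  - name: null-2
    group: "null"
    synthetic:
      design: {trials_per_bin: 200, include_zero: false}
      wave: {sigma0: 200.0, amplitude: 0.0}
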