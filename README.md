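# rtwave

Analysis pipeline for detecting **wave-like patterns in the dispersion of
response times** along the numerosity-error dimension of behavioral
experiments.

In numerosity-estimation tasks, participants judge how many items (dots) a
stimulus contains, either by entering a number or by comparing against a
target.  For each trial one can form the *differential*
`d = actual numerosity − estimate (or target)` and, per value of `d`, the
standard deviation `σ_RT(d)` of the response times.  Plotted along `d`,
this dispersion profile can show an oscillatory, mirror-symmetric shape
about `d = 0`.  `rtwave` quantifies that mirror symmetry and estimates how
likely it is to arise by chance:

1. **Dispersion profiling** — bin trials by `d`, compute per-bin count,
   mean RT and sample SD (after optional error exclusion and RT outlier
   trimming at `k` SDs from the global or per-participant mean).
2. **Arm-symmetry statistic** — normalize the SD profile to [0, 1], split
   it at an axis (default `d = 0`) into a negative and positive arm indexed
   by eccentricity `|d − axis|`, resample each arm with a cubic smoothing
   spline onto a common `K = 100`-point grid, and compute the Pearson
   product-moment correlation `r` between the two arm curves.  `r → 1`
   for a mirrored wave, `r ≈ 0` for unrelated arms.
3. **Monte Carlo null** — draw structureless profiles with each point iid
   `N(μ, σ)` (defaults μ = 0.44, σ = 0.27, the pooled moments of
   normalized reference profiles) on the same differential grid, score them
   with the identical procedure, and report
   `p̂ = #{r_sim > r_observed} / reps`.
4. **Group inference** — compare per-dataset `p̂` values between groups of
   datasets with a homoscedastic two-sample two-tailed t-test
   (`df = n₁ + n₂ − 2`).

A synthetic-data generator produces trial tables with a configurable
sinusoidal SD envelope (mirrored, phase-shifted, or flat), the three
empirical trial-count shapes (flat, bipartite-exponential, bell), and
free-entry or two-choice response structure — so the entire chain runs and
can be validated with no external data.

## Worked example

```python
from rtwave import (DesignConfig, WaveParams, generate_trials, build_profile,
                    arm_symmetry, NullConfig, null_probability)

design = DesignConfig(trials_per_bin=200, include_zero=False)
wave = WaveParams(sigma0=200.0, amplitude=100.0, wavelength=5.0)
trials = generate_trials(design, wave, seed=1)
print(f"{len(trials)} trials across {trials['differential'].nunique()} differentials")

profile = build_profile(trials, min_count=5)
sym = arm_symmetry(profile, axis=0, K=100)
print(f"arm correlation r = {sym.r:.3f}")

null_cfg = NullConfig(abscissae=profile["differential"].tolist(),
                      mu=0.44, sigma=0.27, reps=10_000, seed=2)
res = null_probability(sym.r, null_cfg)
print(f"chance probability p_hat = {res.p_hat:.4f} "
      f"(null r: mean {res.r_sim_mean:.3f}, SD {res.r_sim_sd:.3f})")
```

prints

```
6000 trials across 30 differentials
arm correlation r = 0.994
chance probability p_hat = 0.0038 (null r: mean -0.003, SD 0.581)
```

The generated wave (amplitude half the baseline SD, wavelength 5
differential units) produces near-perfectly mirrored arms (r = 0.994);
under the structureless null, fewer than 0.4% of random profiles reach
that correlation, so the mirrored wave would be very unlikely by chance.
With `amplitude=0.0` the same pipeline returns r scattered around 0 and
`p̂` roughly uniform on (0, 1).

## Command line

```bash
rtwave simulate --config examples/wave.yaml --seed 1 --out trials.tsv
rtwave analyze  --config examples/dataset.yaml --seed 1 --out report.json
rtwave study    --config examples/study.yaml   --seed 1 --out study.json
rtwave plot     --input trials.tsv --out panels.png
```

Configuration files are YAML; `examples/` documents the schema (dataset
configs take an `input_path` *or* a `synthetic` block, a `filter` block
with `outlier_k` / `outlier_scope` / `drop_errors`, and analysis
parameters `axis`, `K`, `smoothing`, `min_count`, plus `null` overrides).
`analyze` and `study` default to 10,000 Monte Carlo repetitions
(SE ≤ 0.005); `--full-reps` switches to 100,000.

## Layout

- `src/rtwave/synthetic_data.py` — wave-envelope trial generator
- `src/rtwave/trial_io.py` — reading, validation, filtering variants
- `src/rtwave/dispersion_profile.py` — per-differential binning, normalization
- `src/rtwave/symmetry_analysis.py` — arm split / spline resample / Pearson r
- `src/rtwave/null_model.py` — Monte Carlo null of the symmetry statistic
- `src/rtwave/group_inference.py` — pooled-variance t-test, group summaries
- `src/rtwave/pipeline.py`, `cli.py` — orchestration, reports, CLI

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
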