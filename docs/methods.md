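# Methods

## The quantity under study

For a trial table with differential `d = actual_n − estimate_or_target`
and response time `rt` (ms), the dispersion profile assigns to each
distinct `d` the triple (count, mean RT, sample SD of RT).  The scientific
question is whether `σ_RT(d)` oscillates along `d` with mirror symmetry
about an axis near `d = 0` — a pattern that would not be expected if task
difficulty changed RT variability monotonically with error magnitude.

The symmetry is measured by a single statistic: split the normalized SD
profile at the axis, re-index both halves by eccentricity `|d − axis|`,
resample each half with a cubic smoothing spline onto a common
`K`-point grid, and take the Pearson correlation `r` of the two curves.

## Preprocessing

- **Error exclusion** (two-choice paradigms): optionally keep only correct
  responses.  Requesting it on a free-entry table (no correctness flags)
  is a configuration error, not a silent no-op.
- **Outlier trimming**: remove trials with `|rt − m| > k·s`, where `(m, s)`
  are the mean and sample SD of RT over the whole table (`global`) or per
  participant (`participant`).  `k` is typically 1.96 or 3; equality at
  the threshold is retained (strictly-greater rule).  Sample SD
  (`n − 1` denominator) is used everywhere; at the trial counts involved
  the choice is immaterial, and it keeps every SD in the package the
  standard inferential estimator.
- **Order**: errors are excluded before outliers are trimmed.  The reverse
  order lets wrong-key lapses with extreme RTs inflate the trimming
  threshold; the fixed order makes the threshold reflect genuine response
  behavior.  (For within-participant trimming the participant moments are
  likewise computed after error exclusion.)

## Profile construction

Bins are the raw integer differentials; an optional `bin_width` groups
neighbors for sparse free-entry data.  Bins with fewer than `min_count`
trials (default 5) are dropped and listed in the profile metadata — an SD
over fewer trials is too noisy to be a meaningful profile point.  Missing
intermediate differentials simply stay absent; the spline interpolates
across gaps.  If fewer than 4 bins survive on either side of zero the
profile carries a warning, since the arm analysis will be impossible or
fragile.

## The arm-symmetry statistic

- **Normalization**: the SD values are linearly mapped to [0, 1]
  (min → 0, max → 1) before splitting.  This matters: the spline's
  smoothing budget is an *absolute* residual allowance, so the fit — and
  hence `r` — depends on the value scale.  Defining the statistic on the
  normalized scale makes it invariant to affine rescaling of the profile
  and puts all datasets on the same smoothing regime.  (With a zero
  budget, i.e. exact interpolation, the scale dependence disappears and
  raw-scale correlation gives the identical `r`.)
- **Axis**: default 0.  A point exactly at the axis belongs to neither
  arm.  Each side needs at least 4 points (a cubic spline needs k + 1
  support points).  An exploratory `search_axis` helper maximizes `r` over
  a small offset grid; it biases `r` upward and is never used in the
  pipeline or the null model.
- **Resampling**: each arm is fit by `scipy.interpolate.UnivariateSpline`
  (degree 3) with smoothing factor `s` = number of arm points under unit
  weights — the implementation's own default convention, which assumes
  roughly unit-variance residuals per point; on [0, 1]-normalized values
  this is a deliberately heavy smoothing that keeps only the coarse shape
  of the arm.  `s` is exposed in every API and config because it is a
  genuine free parameter of the procedure.  The spline is evaluated at
  `K = 100` equally spaced eccentricities spanning that arm's own range,
  so arms of unequal extent are compared index-by-index on their
  normalized grids — a mirror comparison of shape, not of absolute
  position.  On smooth profiles, `r` changes by < 0.02 for any `K ≥ 100`.
- **Correlation**: Pearson product-moment (`numpy.corrcoef`).  Constant
  input raises a degenerate-input error rather than returning NaN.

## Monte Carlo null

The null hypothesis is a structureless profile: each of the `m` profile
values drawn iid from `N(μ, σ)` and placed on the *real* profile's
differential grid — point counts and geometry matter to the spline, so the
simulated profiles share them.  Defaults `(μ, σ) = (0.44, 0.27)` are the
pooled mean and sample SD of the aggregated normalized reference
profiles; `pooled_null_params` recomputes them for any collection of
profiles.  Simulated values are not re-normalized: a nonzero-budget spline
fit on draws already on the [0, 1] scale matches the data path, and
re-normalizing each draw would only introduce a degenerate-case branch.

The exceedance estimate is `p̂ = #{r_sim > r_obs} / reps` (strict
inequality; a conservative `(#{r_sim ≥ r_obs} + 1)/(reps + 1)` variant is
available).  By construction `p̂` is exactly 1 at `r_obs = −1` and 0 at
`r_obs = +1`, is non-increasing in `r_obs` for a fixed seed, and — the key
calibration property — is approximately Uniform(0, 1) when `r_obs` itself
comes from the null generator (verified by a Kolmogorov–Smirnov test in
the suite).  Default 100,000 repetitions (Monte Carlo SE ≤ 0.0016); the
CLI quick mode uses 10,000 (SE ≤ 0.005).  One root seed drives a single
`numpy` Generator whose draws are taken as one block, so results are
reproducible and the block could be partitioned into substreams for
parallel execution.

## Group inference

Per-dataset `p̂` values are compared between exactly two group labels with
the homoscedastic (pooled-variance) two-sample two-tailed t-test,
`df = n₁ + n₂ − 2`.  No Welch correction and no multiple-testing
adjustment: the design produces a single group-level test, and per-dataset
`p̂` values are descriptive.  Group labels come from the study
configuration, never from the data.

## Synthetic generator

The generator emulates the features of real numerosity datasets that the
analysis is sensitive to:

- **SD envelope**: `σ(d) = σ₀ + A·sin(2π|d|/λ + φ [+ Δφ on the negative
  arm])`.  `Δφ = 0` gives an exactly mirrored envelope; `Δφ = π` an
  anti-phase negative control; `A = 0` the null condition.  Validity
  requires `σ₀ − A > 0`.  The amplitude and wavelength of any real effect
  are not established quantities; the defaults used in tests
  (`σ₀ = 200 ms`, `A = 100 ms`, `λ = 5`) are calibration/power settings
  chosen to be detectable at realistic trial counts, not estimates.
- **Counts per bin**: flat (counterbalanced two-choice designs),
  bipartite-exponential `round(n₀·e^(−0.3|d|))` (free-entry pile-up near
  the correct answer; decay rate configurable), or bell-shaped
  (discretized normal, SD defaulting to range/4).  The empirical count
  shapes constrain only the shape family, not its parameters, so both
  knobs are exposed.  Counts are floored at 2 so a sample SD exists.
- **RTs**: normal truncated at 0 with the target mean (~0.9–5.6 s in real
  designs; default 1000 ms) and SD `σ(d)` — truncation keeps per-bin SD
  directly controllable by the envelope (at `mean ≫ σ` the truncation
  bias is negligible; the suite checks empirical per-bin SD tracks the
  envelope within sampling error).  A moment-matched lognormal option
  exists for users who want realistic RT skew; the dispersion envelope is
  then still matched in mean/SD but the analysis makes no distributional
  assumption anyway.
- **Structure deliberately absent**: no participant-level random effects
  beyond round-robin id assignment, no sequential (learning/fatigue)
  effects, no RT–accuracy interaction beyond the logistic accuracy model
  in `|d|` for two-choice designs, and the optional difficulty gradient on
  mean RT is off by default so dispersion structure is isolated from mean
  structure.  Passing tests therefore demonstrate the *procedure* detects
  mirrored dispersion waves and is calibrated under its null — not that
  any real dataset contains such waves.
- The `d = 0` bin is generated for free-entry designs and omitted for
  two-choice designs (a response at the exact target has no higher/lower
  answer); configurable.

## Numerical and design choices

- Differential sign convention: `actual − estimate`.  All symmetry logic
  is sign-agnostic (flipping all signs swaps the arms and leaves `r`
  unchanged, which the suite asserts).
- Degenerate inputs raise typed errors (`DegenerateInputError`,
  `InsufficientArmError`, ...) rather than propagating NaNs.
- Profile-side spline fits and the null simulation use the identical
  geometry code path, so data and null are scored by the same procedure.
- Stage accounting is exact: trials in = trials retained + error
  exclusions + outlier trims, and every report echoes its full effective
  configuration and seeds.
- Test problem sizes (e.g. 2,000 null repetitions × 200 calibration
  replications, 50 power seeds) were chosen so the Monte Carlo error is
  well below the asserted margins while the whole suite stays
  interactive-fast.

## Known limitations

- The Monte Carlo null treats profile points as independent draws; it does
  not model the weak dependence induced by global normalization of real
  profiles, nor offer a trial-label permutation null.
- No spectral estimate of the wave's frequency or phase-alignment
  correction is provided; a mirrored but phase-misaligned pattern scores a
  low `r` by design.
- Axis placement is user-specified; the exploratory axis search is biased
  and excluded from inference.
- Free-entry designs with very sparse extreme differentials rely on
  `min_count` dropping and spline interpolation across gaps; profiles with
  fewer than 4 usable bins per side cannot be analyzed at all.
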