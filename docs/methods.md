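# Methods

## Problem and model

During an incremental cardiopulmonary exercise test, breath-by-breath
analysis yields one tidal-volume (VT, mL) and one breathing-frequency
(BF, breaths/min) value per respiratory cycle. The dispersion of these
values around their exercise trend is a candidate objective marker of
dysfunctional breathing (erratic breathing, frequent sighs). The
statistical model is

    y_i = T(i) + e_i,   i = 1..N,

with T a smooth, monotone rest-to-peak trend over the cycle index and
e_i zero-mean noise of standard deviation σ — the *true dispersion* to
be estimated. The cycle index is used as the time proxy because that is
what breath-by-breath exports provide.

## Estimators

- **Plain SD**: sample SD about the mean (`n−1` denominator, as
  everywhere in the package). Correct when T is constant; inflated by
  any trend.
- **MSD_n**: mean of the sample SDs of all fully contained length-n
  sliding windows (stride 1, no edge padding). Within a window the
  trend contributes little, but each window SD is biased low by the
  factor c4(n) = √(2/(n−1))·Γ(n/2)/Γ((n−1)/2); `sd_bias_factor`
  computes it via log-gamma. Larger n reduces that bias but admits more
  trend.
- **LOESS_span residual SD**: degree-2 locally weighted regression on
  the cycle index. For target i the q = max(degree+2, ⌈span·N⌉)
  nearest neighbours are weighted by the tricube
  (1 − (d/d_max)³)³ and a weighted least-squares quadratic is fitted;
  the fitted value is its evaluation at i. The dispersion estimate is
  the sample SD of y − ŷ. Local quadratics reproduce polynomials of
  degree ≤ 2 exactly, so the estimator is invariant to affine trends
  per replicate, not merely on average.

### Numerical choices

- Evaluation is exact at every point (no interpolation grid) and there
  are no robustness iterations; weights follow the conventional
  nearest-neighbour tricube scheme. Against an R `loess` using its
  default interpolation surface, means may differ below the 0.5% level.
- Ties in neighbour distance are broken toward the lower index (stable
  argsort). Coincident abscissae that leave d_max = 0, or a weighted
  design of deficient rank, raise an error naming the target index;
  neither can occur with integer cycle indices.
- The local abscissa is centred at the target and scaled by d_max
  before solving, so the fitted value is the local intercept and the
  3×3 normal systems stay well conditioned even at N = 300.
- With fixed abscissae 1..N the fit is a linear smoother; the N×N
  smoother matrix depends only on (N, span, degree) and is cached, so a
  Monte-Carlo study is one matrix product per (scenario, span).

## Synthetic-data generator

Each replicate is built flat → sighs (optional) → trend:

1. **Flat series**: N i.i.d. Normal(mean, σ) draws, then re-centred and
   rescaled so the sample mean and sample SD equal the nominal values
   *exactly*. This makes the ground truth exact per replicate (the
   plain SD of flat data has zero spread across replicates) at the cost
   of a weak coupling between cycles: the mean MSD_n over rescaled
   replicates sits about 0.1% above the i.i.d. prediction σ·c4(n), a
   shift visible only beyond ~2,000 replicates.
2. **Sighs** (VT only): replacement values from Normal(3500, 200) mL at
   gaps drawn from Normal(15, 3) cycles, rounded and floored at 4; the
   first gap is drawn from the same distribution starting at cycle 0,
   and positions past N are discarded. After insertion the series is
   rescaled about its post-insertion mean so the overall sample SD is
   exactly the nominal σ again — sigh contamination changes the shape
   of the dispersion, not its amount. The mean is re-centred by the
   same affine map; whether to restore the pre-sigh mean instead is
   immaterial to every estimator here (all are translation invariant).
3. **Trend**: an additive offset T(i) − T(1) anchored at
   T(1) = rest mean and T(N) = end mean, so sighs ride the trend like
   every other breath. Shapes:
   - linear: T(i) = rest + (end−rest)·(i−1)/(N−1)
   - logarithmic: T(i) = rest + (end−rest)·ln(i)/ln(N)
   - exponential: T(i) = rest + (end−rest)·(e^((i−1)/c) − 1)/(e^((N−1)/c) − 1),
     c = 40 cycles by default.

   The logarithmic and exponential forms are this package's
   parameterisation of "markedly curved" trends anchored at the same
   endpoints; c is configurable (`TrendSpec.shape_constant`) so other
   curvatures can be swapped in. Published benchmark values for
   *trended moving-SD* cells depend on the exact curvature used and are
   therefore not treated as exact oracles by the tests; raw-SD cells
   under these forms agree with the published ones to ~1.5–2.5%.

Default parameters are the cohort-derived study conditions: rest/peak
means 790→2130 mL (VT) and 18→39/min (BF), N = 300 cycles, dispersion
levels 60/270/500 mL and 2/4/6 breaths/min, sighs as above.

**Randomness.** One master seed per study; replicate r uses the
sub-stream `SeedSequence(seed, spawn_key=(r,))`, so any replicate is
individually reproducible and replicates are mutually independent.

**What the generator does not emulate**: within-breath flow/volume
waveforms, autocorrelated noise, hyperventilation episodes, ramp or
recovery protocols (a single rest→peak trend only), or sighs whose
amplitude stays fixed while VT rises (here sighs are trended with
everything else, a deliberately harder case). Passing tests therefore
demonstrate correct recovery of dispersion under these idealised
conditions, not clinical validity on real traces.

## Bias/precision study

For each (parameter, σ, trend, sighs) × method cell, `n_reps`
replicates are generated, the estimator applied to each, and the cell
summarised by the mean estimate, bias (mean − σ), precision (SD of
estimates) and Monte-Carlo standard error (precision/√n_reps). All
methods and all trend shapes within one σ level share the same
replicate streams (common random numbers), which sharpens method
contrasts; marginal summaries are unaffected. Grids default to 1,000
replicates — Monte-Carlo standard errors are then already an order of
magnitude below the effects of interest — and scale to any count.

## Per-phase workflow

Real tests traverse rest, warm-up, loaded exercise and recovery, and
the trend reverses sharply at transitions; a single whole-test LOESS
adapts slowly there and inflates residuals. `per_phase_dispersion`
fits an independent span-0.75 quadratic LOESS inside each
caller-supplied phase (≥ 8 cycles each; segments contiguous and
exhaustive) and reports the residual SD per phase plus a pooled value:
the sample SD, with a single n−1 denominator, of all residuals
concatenated across phases — so a single-phase segmentation reduces
exactly to the whole-series estimator. Between three and four phases
both work; the segmentation type imposes no fixed number. Fitted
curves and per-phase residual summaries (mean, SD, skewness) are
returned for the recommended visual check of fit quality. Automatic
phase detection is deliberately out of scope: phases come from operator
annotation or protocol timestamps.

## Design choices in brief

- `n−1` denominator for every SD (required for the c4 analysis to
  apply).
- Exact-SD rescaling of flat replicates: makes the ground truth exact
  and the plain-SD flat cells spread-free; side effect on MSD means
  noted above.
- MSD uses fully contained windows only; no edge padding.
- Sigh gaps floored at 4 cycles; no sigh forced at cycle 1.
- Delimiter (comma/semicolon/tab) and decimal comma are auto-detected
  on input; units are fixed to mL and breaths/min, with a warning when
  a VT column looks like litres (median < 15).

## Known limitations

- The LOESS estimator overestimates σ when an extreme curvature meets
  a very small σ (the local quadratic cannot fully track the bend, and
  the unmodelled trend leaks into the residuals); in that corner a
  short-window moving SD can be less biased. This is inherent to the
  method, and is the main reason span 0.75 (not 0.5 or 1) is the
  recommended compromise.
- No robust (iteratively reweighted) LOESS: isolated sighs slightly
  attract the local fit. In the simulated scenarios the effect on the
  residual SD is negligible.
- Estimates carry no confidence intervals; the Monte-Carlo framework
  quantifies estimator (not per-test) uncertainty.
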