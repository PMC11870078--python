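# breathvar

Objective quantification of the dispersion of breath-by-breath
parameters — tidal volume (VT, mL) and breathing frequency (BF,
breaths/min) — during cardiopulmonary exercise testing (CPET).

Erratic breathing and frequent sighing produce visibly "noisy"
cycle-by-cycle VT and BF traces, and their dispersion is a candidate
objective marker of dysfunctional breathing. The difficulty is the
exercise trend: both VT and BF rise during a test, with a shape that
varies between patients, so a plain standard deviation confounds trend
with dispersion. `breathvar` is for researchers and CPET-software
developers who need a trend-robust dispersion estimate and a way to
validate it.

## Methods

Two families of estimators of the dispersion σ of a series
y₁..y_N around its trend:

- **Moving standard deviation, MSD_n** — the mean of the sample SDs of
  all N−n+1 sliding windows of n consecutive cycles. Short windows see
  little trend but inherit the small-sample bias of the SD: under
  normality E[s] = c4(n)·σ with
  c4(n) = √(2/(n−1))·Γ(n/2)/Γ((n−1)/2) < 1
  (≈ 4% underestimation at n = 7).
- **LOESS residual SD, LOESS_span** — fit the trend by locally
  estimated scatterplot smoothing (for each cycle, a tricube-weighted
  least-squares polynomial of degree 2 over the ⌈span·N⌉ nearest
  cycles) and report the sample SD of the residuals y − ŷ. Because the
  local fits reproduce polynomials of degree ≤ 2 exactly, the estimator
  is invariant to any linear trend by construction.

A Monte-Carlo framework (`breathvar.synthdata`, `breathvar.study`)
validates both: replicate series with *exactly* known true SD are
generated (normal draws, re-centred and rescaled), optionally
contaminated with sighs (Normal(3500, 200) mL replacement values about
every 15 cycles, never closer than 4 apart), trended (linear,
logarithmic, or exponential, anchored at the rest and peak means), and
fed to every estimator; bias (mean estimate − σ) and precision (SD of
estimates) are tabulated per scenario. Across these simulations the
span-0.75 LOESS combines low bias, high precision, and low sensitivity
to trend shape, which is why it is the default in the per-phase
workflow (`breathvar.phases`) for real multi-phase tests.

## Worked example

```python
from breathvar import (ScenarioSpec, ParameterKind, MethodSpec, Method,
                       run_cell)

cell = run_cell(
    ScenarioSpec(ParameterKind.BF_PER_MIN, true_sd=4.0, n_reps=1000, seed=42),
    MethodSpec(Method.LOESS_RESID_SD, span=0.75),
)
print(f"mean={cell.mean_estimate:.3f} bias={cell.bias:+.3f} "
      f"precision={cell.precision:.3f}")
```

prints

```
mean=3.973 bias=-0.027 precision=0.018
```

1,000 flat BF series of 300 cycles with true SD 4/min were generated;
the span-0.75 LOESS residual SD recovers the truth with a bias of only
−0.027 breaths/min and a replicate-to-replicate spread of 0.018. The
same scenario with `MethodSpec(Method.MSD, window_n=7)` gives
`mean=3.842 bias=-0.158 precision=0.057` — the expected c4(7) ≈ 4%
small-window underestimation and a three-fold worse precision.

From the shell:

```sh
breathvar simulate --param vt --sd 270 --trend log --sighs --n 300 --seed 42 --out series.csv
breathvar estimate --in series.csv --param vt --method loess --span 0.75
# -> LOESS_0.75,span=0.75,273.718
breathvar study --preset table_bf --reps 1000 --seed 7 --out results.csv --plot fig.png
breathvar phases --in test.csv --span 0.75 --phases rest:1-60,exercise:61-240,recovery:241-300
```

The estimate of 273.7 mL for a sigh-contaminated, log-trended series
whose true dispersion is 270 mL illustrates the method's trend
robustness on a single replicate.

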