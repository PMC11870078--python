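"""Synthetic breath-by-breath series with known true dispersion.

The validation strategy for dispersion estimators is Monte Carlo: generate
series whose ground-truth dispersion is known exactly, optionally
contaminate them with sighs, superimpose an exercise trend, and measure
how well each estimator recovers the truth.  This module generates those
series.

Three building blocks, composed in this order:

1. :func:`simulate_flat_series` — i.i.d. normal values, then re-centred
   and rescaled so the sample mean and sample SD (``n-1`` denominator)
   equal the requested values *exactly*.  The rescaled sample SD is the
   "true dispersion" every estimator is judged against.
2. :func:`insert_sighs` — replaces randomly spaced cycles with draws from
   a high-mean normal distribution (a sigh is an isolated, much larger
   breath), then rescales the whole series back to the target SD.
3. :func:`apply_trend` — adds a deterministic rest-to-peak trend curve
   (linear, logarithmic or exponential) anchored at the first and last
   cycle; sighs receive the same additive offset as their neighbours.

Default scenario parameters reflect breath-by-breath CPET data from
adults with dysfunctional breathing: resting VT 790 mL rising to 2130 mL
at peak exercise, resting BF 18/min rising to 39/min, 300 respiratory
cycles per test, dispersion levels of 60/270/500 mL (VT) and
2/4/6 breaths/min (BF), and sighs near 3500 mL about every 15 cycles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .series import BreathSeries, ParameterKind

__all__ = [
    "TrendShape",
    "TrendSpec",
    "SighSpec",
    "ScenarioSpec",
    "simulate_flat_series",
    "insert_sighs",
    "apply_trend",
    "trend_offsets",
    "base_replicate",
    "replicate",
    "generate_replicates",
    "replicate_rng",
]

logger = logging.getLogger(__name__)


class TrendShape(str, Enum):
    FLAT = "flat"
    LINEAR = "linear"
    LOGARITHMIC = "logarithmic"
    EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class TrendSpec:
    """Shape of the rest-to-peak exercise trend.

    ``shape_constant`` is the per-cycle curvature scale of the
    exponential shape: T(i) ∝ exp((i-1)/c), so smaller values bend the
    curve harder toward the end of the test.  It is ignored by the other
    shapes.
    """

    shape: TrendShape = TrendShape.FLAT
    shape_constant: float = 40.0

    def __post_init__(self):
        object.__setattr__(self, "shape", TrendShape(self.shape))
        if self.shape_constant <= 0:
            raise ValueError("shape_constant must be positive")


@dataclass(frozen=True)
class SighSpec:
    """Sigh contamination model for VT series.

    Sighs are draws from Normal(sigh_mean, sigh_sd) that *replace*
    existing cycle values.  Successive sighs are separated by gaps drawn
    from Normal(interval_mean, interval_sd), rounded to the nearest
    integer and floored at ``min_gap`` cycles.
    """

    sigh_mean: float = 3500.0
    sigh_sd: float = 200.0
    interval_mean: float = 15.0
    interval_sd: float = 3.0
    min_gap: int = 4

    def __post_init__(self):
        if self.sigh_sd <= 0 or self.interval_sd <= 0:
            raise ValueError("sigh_sd and interval_sd must be positive")
        if self.min_gap < 1:
            raise ValueError("min_gap must be >= 1")
        if self.interval_mean <= self.min_gap:
            raise ValueError("interval_mean must exceed min_gap")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulation scenario."""

    parameter_kind: ParameterKind
    true_sd: float
    trend: TrendSpec = TrendSpec()
    sighs: SighSpec | None = None
    n_cycles: int = 300
    rest_mean: float | None = None
    end_mean: float | None = None
    n_reps: int = 10_000
    seed: int = 0

    #: Cohort-based rest/peak means per parameter.
    _DEFAULT_MEANS = {
        ParameterKind.VT_ML: (790.0, 2130.0),
        ParameterKind.BF_PER_MIN: (18.0, 39.0),
    }

    def __post_init__(self):
        object.__setattr__(
            self, "parameter_kind", ParameterKind(self.parameter_kind)
        )
        rest, end = self._DEFAULT_MEANS[self.parameter_kind]
        if self.rest_mean is None:
            object.__setattr__(self, "rest_mean", rest)
        if self.end_mean is None:
            object.__setattr__(self, "end_mean", end)
        if self.n_cycles < 2:
            raise ValueError("n_cycles must be >= 2")
        if self.true_sd <= 0:
            raise ValueError("true_sd must be positive")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if (
            self.trend.shape is not TrendShape.FLAT
            and self.end_mean < self.rest_mean
        ):
            raise ValueError("end_mean must be >= rest_mean for a rising trend")
        if self.sighs is not None and self.parameter_kind is not ParameterKind.VT_ML:
            raise ValueError("sighs are only modelled for tidal volume series")


# ---------------------------------------------------------------------------
# generation


def simulate_flat_series(
    n_cycles: int,
    mean: float,
    true_sd: float,
    rng: np.random.Generator,
    parameter_kind: ParameterKind = ParameterKind.VT_ML,
) -> BreathSeries:
    """Normal series with *exact* sample mean and sample SD.

    Draws ``n_cycles`` i.i.d. Normal(mean, true_sd) values, then
    re-centres and rescales the deviations so that the returned series
    has sample mean ``mean`` and sample SD (``n-1`` denominator)
    ``true_sd`` to machine precision.  ``true_sd = 0`` yields a constant
    series.
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    if true_sd < 0:
        raise ValueError("true_sd must be non-negative")
    if true_sd == 0:
        return BreathSeries(np.full(n_cycles, float(mean)), parameter_kind)
    draws = rng.normal(mean, true_sd, size=n_cycles)
    values = _rescale_exact(draws, mean, true_sd)
    return BreathSeries(values, parameter_kind)


def _rescale_exact(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Affine map to exact sample mean and sample SD (ddof=1)."""
    centred = values - values.mean()
    s = centred.std(ddof=1)
    if s == 0:
        raise ValueError("cannot rescale a constant series to a positive SD")
    return mean + centred * (sd / s)


def _draw_sigh_positions(
    n_cycles: int, spec: SighSpec, rng: np.random.Generator
) -> np.ndarray:
    """1-based sigh cycle indices with gaps >= min_gap.

    The first gap is drawn from the same distribution as the rest,
    counted from cycle 0 (no sigh is forced at cycle 1); positions past
    the end of the series are discarded.
    """
    positions = []
    pos = 0
    while True:
        gap = int(round(rng.normal(spec.interval_mean, spec.interval_sd)))
        pos += max(gap, spec.min_gap)
        if pos > n_cycles:
            break
        positions.append(pos)
    return np.asarray(positions, dtype=int)


def insert_sighs(
    series: BreathSeries,
    spec: SighSpec,
    target_sd: float,
    rng: np.random.Generator,
) -> BreathSeries:
    """Replace randomly spaced cycles with sighs, keeping the overall SD.

    Selected cycle values are replaced (not added to) by draws from
    Normal(sigh_mean, sigh_sd).  Afterwards the whole series is rescaled
    about its post-insertion mean so the overall sample SD equals
    ``target_sd`` exactly — the contaminated series keeps the same true
    dispersion as an uncontaminated one, only its shape differs.

    Expects a flat (untrended) series; the trend is applied afterwards so
    that sighs rise with exercise like every other breath.
    """
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    if series.n_cycles <= spec.min_gap:
        logger.warning(
            "series of %d cycles too short to hold a sigh; returned unmodified",
            series.n_cycles,
        )
        return series
    positions = _draw_sigh_positions(series.n_cycles, spec, rng)
    if positions.size == 0:
        logger.warning("no sigh fitted in %d cycles; returned unmodified",
                       series.n_cycles)
        return series
    values = series.values.copy()
    values[positions - 1] = rng.normal(spec.sigh_mean, spec.sigh_sd,
                                       size=positions.size)
    values = _rescale_exact(values, values.mean(), target_sd)
    return series.with_values(values, sigh_positions=positions)


def trend_offsets(
    n_cycles: int, spec: TrendSpec, rest_mean: float, end_mean: float
) -> np.ndarray:
    """Additive trend offsets T(i) - T(1) for cycles i = 1..N.

    The trend curve T is anchored at T(1) = rest_mean and
    T(N) = end_mean:

    - linear:       T(i) = rest + (end-rest) * (i-1)/(N-1)
    - logarithmic:  T(i) = rest + (end-rest) * ln(i)/ln(N)
    - exponential:  T(i) = rest + (end-rest) * (e^((i-1)/c) - 1)
                                              / (e^((N-1)/c) - 1)

    with c = ``spec.shape_constant``.  Flat returns all zeros.
    """
    i = np.arange(1, n_cycles + 1, dtype=float)
    span = end_mean - rest_mean
    if spec.shape is TrendShape.FLAT:
        return np.zeros(n_cycles)
    if spec.shape is TrendShape.LINEAR:
        u = (i - 1) / (n_cycles - 1)
    elif spec.shape is TrendShape.LOGARITHMIC:
        u = np.log(i) / math.log(n_cycles)
    elif spec.shape is TrendShape.EXPONENTIAL:
        c = spec.shape_constant
        u = np.expm1((i - 1) / c) / math.expm1((n_cycles - 1) / c)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown trend shape {spec.shape!r}")
    return span * u


def apply_trend(
    series: BreathSeries,
    spec: TrendSpec,
    rest_mean: float,
    end_mean: float,
) -> BreathSeries:
    """Superimpose the exercise trend on a flat series.

    Returns a series with ``values[i] + (T(i) - T(1))``; a flat spec
    returns the input unchanged.  Because the offset is purely additive,
    sigh cycles move with the trend exactly like their neighbours.
    """
    if spec.shape is TrendShape.FLAT:
        return series
    offsets = trend_offsets(series.n_cycles, spec, rest_mean, end_mean)
    return series.with_values(series.values + offsets)


# ---------------------------------------------------------------------------
# replicate streams


def replicate_rng(seed: int, rep: int) -> np.random.Generator:
    """Generator for replicate ``rep`` of the stream with master ``seed``.

    Each replicate owns an independent, individually reproducible
    sub-stream derived from (seed, rep).
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


def base_replicate(spec: ScenarioSpec, rep: int) -> BreathSeries:
    """One pre-trend replicate: flat series plus optional sighs."""
    rng = replicate_rng(spec.seed, rep)
    series = simulate_flat_series(
        spec.n_cycles, spec.rest_mean, spec.true_sd, rng, spec.parameter_kind
    )
    if spec.sighs is not None:
        series = insert_sighs(series, spec.sighs, spec.true_sd, rng)
    return series


def replicate(spec: ScenarioSpec, rep: int) -> BreathSeries:
    """One complete replicate: flat -> sighs (optional) -> trend."""
    return apply_trend(
        base_replicate(spec, rep), spec.trend, spec.rest_mean, spec.end_mean
    )


def generate_replicates(spec: ScenarioSpec) -> list[BreathSeries]:
    """All ``spec.n_reps`` replicates of a scenario.

    Replicate ``r`` can be regenerated individually with
    :func:`replicate`.
    """
    return [replicate(spec, r) for r in range(spec.n_reps)]
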