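"""Per-phase LOESS dispersion for multi-phase exercise tests.

A real CPET traverses distinct phases — rest, warm-up, loaded exercise,
recovery — and the trend direction can reverse abruptly at the
transitions.  A single LOESS over the whole test adapts slowly to such
turns, inflating residuals near phase boundaries.  The recommended
procedure is therefore to fit an independent LOESS (degree 2, span 0.75
by default) *within* each phase and report the residual SD per phase
and pooled over all phases.

Phase boundaries are caller-supplied (an annotated phase column or
explicit cycle ranges); automatic phase detection is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import loess_fit
from .series import PHASE_LABELS, BreathSeries

__all__ = ["Phase", "PhaseSegmentation", "PhaseDispersion", "per_phase_dispersion",
           "diagnostics"]

#: Fewest cycles on which a degree-2 local fit at span 0.75 is accepted.
MIN_PHASE_LENGTH = 8


@dataclass(frozen=True)
class Phase:
    """One contiguous phase: 1-based inclusive cycle range."""

    label: str
    start_cycle: int
    end_cycle: int

    def __post_init__(self):
        if self.label not in PHASE_LABELS:
            raise ValueError(
                f"unknown phase label {self.label!r}; expected one of {PHASE_LABELS}"
            )
        if self.start_cycle < 1 or self.end_cycle < self.start_cycle:
            raise ValueError(f"invalid cycle range in phase {self.label!r}")

    @property
    def length(self) -> int:
        return self.end_cycle - self.start_cycle + 1


@dataclass(frozen=True)
class PhaseSegmentation:
    """Ordered, contiguous, non-overlapping phases covering 1..N."""

    phases: tuple[Phase, ...]

    def __post_init__(self):
        phases = tuple(
            p if isinstance(p, Phase) else Phase(*p) for p in self.phases
        )
        if not phases:
            raise ValueError("segmentation needs at least one phase")
        expected_start = 1
        for p in phases:
            if p.start_cycle != expected_start:
                raise ValueError(
                    f"phase {p.label!r} starts at cycle {p.start_cycle}, "
                    f"expected {expected_start} (phases must be contiguous)"
                )
            if p.length < MIN_PHASE_LENGTH:
                raise ValueError(
                    f"phase {p.label!r} has {p.length} cycles; "
                    f"at least {MIN_PHASE_LENGTH} are needed for a local fit"
                )
            expected_start = p.end_cycle + 1
        object.__setattr__(self, "phases", phases)

    @property
    def n_cycles(self) -> int:
        return self.phases[-1].end_cycle

    @classmethod
    def from_labels(cls, labels) -> "PhaseSegmentation":
        """Build a segmentation from a per-cycle label sequence."""
        labels = list(labels)
        phases = []
        start = 1
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start - 1]:
                phases.append(Phase(labels[start - 1], start, i))
                start = i + 1
        return cls(tuple(phases))


@dataclass(frozen=True)
class PhaseDispersion:
    """Per-phase and pooled residual-SD estimates for one series."""

    segmentation: PhaseSegmentation
    span: float
    per_phase_sd: dict
    pooled_sd: float
    fitted: np.ndarray
    residuals: np.ndarray


def per_phase_dispersion(
    series: BreathSeries,
    segmentation: PhaseSegmentation,
    span: float = 0.75,
    degree: int = 2,
) -> PhaseDispersion:
    """Independent LOESS per phase; residual SD per phase and pooled.

    The pooled value is the sample SD (single ``n-1`` denominator) of
    all residuals concatenated across phases, so with a single phase it
    coincides with the whole-series LOESS residual SD.  Fitted curves
    are returned for visual QC overlays.
    """
    if segmentation.n_cycles != series.n_cycles:
        raise ValueError(
            f"segmentation covers {segmentation.n_cycles} cycles, "
            f"series has {series.n_cycles}"
        )
    fitted = np.empty(series.n_cycles)
    per_phase_sd = {}
    for phase in segmentation.phases:
        sl = slice(phase.start_cycle - 1, phase.end_cycle)
        x = np.arange(1, phase.length + 1, dtype=float)
        try:
            fit = loess_fit(x, series.values[sl], span, degree)
        except ValueError as err:
            raise ValueError(f"phase {phase.label!r}: {err}") from err
        fitted[sl] = fit.fitted
        per_phase_sd[phase.label] = float(fit.residuals.std(ddof=1))
    residuals = series.values - fitted
    return PhaseDispersion(
        segmentation=segmentation,
        span=span,
        per_phase_sd=per_phase_sd,
        pooled_sd=float(residuals.std(ddof=1)),
        fitted=fitted,
        residuals=residuals,
    )


def diagnostics(series: BreathSeries, result: PhaseDispersion) -> pd.DataFrame:
    """Residual summaries per phase for visual quality control.

    One row per phase: residual mean, SD and skewness, plus the data and
    fitted-value ranges — enough to judge whether the local fit tracked
    the phase and left roughly centred, symmetric residuals.
    """
    rows = []
    for phase in result.segmentation.phases:
        sl = slice(phase.start_cycle - 1, phase.end_cycle)
        resid = result.residuals[sl]
        fit = result.fitted[sl]
        data = series.values[sl]
        rows.append({
            "phase": phase.label,
            "start_cycle": phase.start_cycle,
            "end_cycle": phase.end_cycle,
            "n_cycles": phase.length,
            "residual_mean": float(resid.mean()),
            "residual_sd": float(resid.std(ddof=1)),
            "residual_skewness": float(stats.skew(resid)) if resid.std() > 0 else 0.0,
            "fitted_min": float(fit.min()),
            "fitted_max": float(fit.max()),
            "data_min": float(data.min()),
            "data_max": float(data.max()),
        })
    return pd.DataFrame(rows)
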