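"""Monte-Carlo bias/precision study of the dispersion estimators.

For each scenario (parameter, true SD, trend shape, sighs on/off) and
each estimator, ``n_reps`` replicate series are generated and the
estimator applied to each.  The study reports, per cell:

- ``mean_estimate`` — mean of the estimates across replicates,
- ``bias`` — mean_estimate minus the true SD,
- ``precision`` — SD of the estimates across replicates (smaller is
  more precise),
- ``mc_se`` — Monte-Carlo standard error of the mean,
  precision / sqrt(n_reps).

All methods within one scenario are evaluated on the *same* replicate
streams (common random numbers), so method contrasts carry less
Monte-Carlo noise than the marginal ``mc_se`` suggests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import estimators, synthdata
from .estimators import Method, MethodSpec
from .series import ParameterKind
from .synthdata import ScenarioSpec, SighSpec, TrendShape, TrendSpec

__all__ = [
    "StudyCell",
    "DEFAULT_METHODS",
    "run_cell",
    "run_table",
    "summarize_bias_precision",
]

#: Estimator battery in standard table order: raw SD, LOESS spans
#: 1/0.75/0.5, moving SD windows 7/11/15/19.
DEFAULT_METHODS = (
    MethodSpec(Method.PLAIN_SD),
    MethodSpec(Method.LOESS_RESID_SD, span=1.0),
    MethodSpec(Method.LOESS_RESID_SD, span=0.75),
    MethodSpec(Method.LOESS_RESID_SD, span=0.5),
    MethodSpec(Method.MSD, window_n=7),
    MethodSpec(Method.MSD, window_n=11),
    MethodSpec(Method.MSD, window_n=15),
    MethodSpec(Method.MSD, window_n=19),
)


@dataclass(frozen=True)
class StudyCell:
    """Bias/precision summary for one (scenario, method) combination."""

    scenario: ScenarioSpec
    method: MethodSpec
    mean_estimate: float
    bias: float
    precision: float
    n_reps_used: int
    monte_carlo_se: float

    def as_record(self) -> dict:
        s = self.scenario
        return {
            "parameter": s.parameter_kind.value,
            "true_sd": s.true_sd,
            "trend": s.trend.shape.value,
            "sighs": s.sighs is not None,
            "n_cycles": s.n_cycles,
            "method": self.method.label,
            "mean": self.mean_estimate,
            "bias": self.bias,
            "precision": self.precision,
            "mc_se": self.monte_carlo_se,
            "n_reps": self.n_reps_used,
        }


def _base_matrix(spec: ScenarioSpec) -> np.ndarray:
    """Pre-trend replicates stacked as rows of an (n_reps, N) matrix."""
    return np.vstack(
        [synthdata.base_replicate(spec, r).values for r in range(spec.n_reps)]
    )


def _cell_from_estimates(
    spec: ScenarioSpec, method: MethodSpec, estimates: np.ndarray
) -> StudyCell:
    mean = float(estimates.mean())
    precision = float(estimates.std(ddof=1)) if estimates.size > 1 else 0.0
    return StudyCell(
        scenario=spec,
        method=method,
        mean_estimate=mean,
        bias=mean - spec.true_sd,
        precision=precision,
        n_reps_used=estimates.size,
        monte_carlo_se=precision / np.sqrt(estimates.size),
    )


def cell_estimates(spec: ScenarioSpec, method: MethodSpec,
                   base: np.ndarray | None = None) -> np.ndarray:
    """Per-replicate estimates for one scenario/method combination.

    ``base`` lets a caller reuse a pre-generated pre-trend matrix; the
    trend offsets are added here (they are deterministic, so sharing the
    base across trends realises common random numbers).
    """
    if base is None:
        base = _base_matrix(spec)
    offsets = synthdata.trend_offsets(
        spec.n_cycles, spec.trend, spec.rest_mean, spec.end_mean
    )
    return estimators.batch_estimate(base + offsets, method)


def run_cell(spec: ScenarioSpec, method: MethodSpec) -> StudyCell:
    """Generate replicates, apply one method, summarise bias/precision."""
    return _cell_from_estimates(spec, method, cell_estimates(spec, method))


def run_table(
    parameter_kind: ParameterKind | str,
    sd_levels,
    trend_shapes,
    methods=DEFAULT_METHODS,
    sighs: bool = False,
    n_reps: int = 1000,
    seed: int = 0,
    n_cycles: int = 300,
) -> pd.DataFrame:
    """Full factorial grid: SD levels x trend shapes x methods.

    Returns one row per cell with columns parameter, true_sd, trend,
    sighs, method, mean, bias, precision, mc_se, n_reps.  Within one SD
    level all trends and methods share the same replicate streams.
    """
    parameter_kind = ParameterKind(parameter_kind)
    sigh_spec = SighSpec() if sighs else None
    records = []
    for sd in sd_levels:
        flat_spec = ScenarioSpec(
            parameter_kind,
            true_sd=float(sd),
            sighs=sigh_spec,
            n_cycles=n_cycles,
            n_reps=n_reps,
            seed=seed,
        )
        base = _base_matrix(flat_spec)
        for shape in trend_shapes:
            spec = replace(flat_spec, trend=TrendSpec(TrendShape(shape)))
            for method in methods:
                estimates = cell_estimates(spec, method, base=base)
                records.append(
                    _cell_from_estimates(spec, method, estimates).as_record()
                )
    return pd.DataFrame.from_records(records)


def format_table(results: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Pivot results into the familiar layout: method rows, trend columns,
    cells formatted ``mean (±precision)``."""
    df = results.copy()
    df["cell"] = [
        f"{m:.{decimals}f} (±{p:.{decimals}f})"
        for m, p in zip(df["mean"], df["precision"])
    ]
    trends = list(dict.fromkeys(df["trend"]))
    methods = list(dict.fromkeys(df["method"]))
    out = df.pivot_table(
        index=["true_sd", "method"], columns="trend", values="cell",
        aggfunc="first", sort=False,
    )
    out = out.reindex(columns=trends)
    out = out.reindex(
        pd.MultiIndex.from_product(
            [sorted(set(df["true_sd"])), methods], names=["true_sd", "method"]
        )
    )
    return out


def summarize_bias_precision(
    results: pd.DataFrame, plot_path: str | None = None
) -> pd.DataFrame:
    """Bias and precision versus true SD, one panel pair per trend.

    Returns a tidy frame (trend, method, true_sd, bias, precision); when
    ``plot_path`` is given, also writes a figure with one row of panels
    per trend shape — bias on the left, precision on the right.
    """
    if len(results) == 0:
        raise ValueError("no study results to summarize")
    report = (
        results[["trend", "method", "true_sd", "bias", "precision"]]
        .drop_duplicates(["trend", "method", "true_sd"])
        .sort_values(["trend", "method", "true_sd"], kind="stable")
        .reset_index(drop=True)
    )
    if plot_path is not None:
        _plot_summary(report, plot_path)
    return report


def _plot_summary(report: pd.DataFrame, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trends = list(dict.fromkeys(report["trend"]))
    fig, axes = plt.subplots(
        len(trends), 2, figsize=(9, 3 * len(trends)), squeeze=False
    )
    for row, trend in enumerate(trends):
        sub = report[report["trend"] == trend]
        for col, quantity in enumerate(["bias", "precision"]):
            ax = axes[row][col]
            for method, grp in sub.groupby("method", sort=False):
                ax.plot(grp["true_sd"], grp[quantity], marker="o", label=method)
            ax.axhline(0.0, color="red", lw=0.8)
            ax.set_title(f"{quantity} — {trend} trend")
            ax.set_xlabel("true SD")
        axes[row][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
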