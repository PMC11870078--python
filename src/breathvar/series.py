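"""Per-cycle breath series container.

A cardiopulmonary exercise test (CPET) analysed breath by breath yields one
value per respiratory cycle for each ventilatory parameter: tidal volume
(VT, mL) or breathing frequency (BF, breaths/min).  :class:`BreathSeries`
is the universal carrier used by the generators, estimators and the
per-phase workflow: an ordered sequence of per-cycle values with an
implicit 1-based cycle index, optional phase annotation and optional
record of which cycles are sighs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = ["ParameterKind", "BreathSeries", "PHASE_LABELS"]

#: Recognised CPET phase labels, in protocol order.
PHASE_LABELS = ("rest", "warmup", "exercise", "recovery")


class ParameterKind(str, Enum):
    """Which breathing parameter a series carries."""

    VT_ML = "vt"
    BF_PER_MIN = "bf"


def _as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"series values must be 1-D, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class BreathSeries:
    """Ordered per-cycle values of one breathing parameter.

    Parameters
    ----------
    values
        One value per respiratory cycle, in parameter units (mL for VT,
        breaths/min for BF).  Cycle ``i`` (1-based) is ``values[i-1]``.
    parameter_kind
        Which parameter the values are.
    phase_labels
        Optional per-cycle phase annotation.  When present, each label
        must occupy one contiguous block of cycles.
    sigh_positions
        Optional 1-based cycle indices whose values are simulated sighs.
    """

    values: np.ndarray
    parameter_kind: ParameterKind
    phase_labels: np.ndarray | None = None
    sigh_positions: np.ndarray | None = field(default=None)

    def __post_init__(self):
        arr = _as_float_array(self.values)
        if arr.size < 2:
            raise ValueError("a breath series needs at least 2 cycles")
        if not np.all(np.isfinite(arr)):
            raise ValueError("series values must all be finite")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "parameter_kind", ParameterKind(self.parameter_kind))

        if self.phase_labels is not None:
            labels = np.asarray(self.phase_labels, dtype=object)
            if labels.shape != arr.shape:
                raise ValueError("phase_labels must match values in length")
            unknown = set(labels) - set(PHASE_LABELS)
            if unknown:
                raise ValueError(f"unknown phase labels: {sorted(unknown)}")
            _check_contiguous(labels)
            object.__setattr__(self, "phase_labels", labels)

        if self.sigh_positions is not None:
            pos = np.asarray(self.sigh_positions, dtype=int)
            if pos.size and (pos.min() < 1 or pos.max() > arr.size):
                raise ValueError("sigh_positions out of 1..N range")
            object.__setattr__(self, "sigh_positions", np.sort(pos))

    @property
    def n_cycles(self) -> int:
        return int(self.values.size)

    @property
    def cycle_index(self) -> np.ndarray:
        """1-based cycle indices, the x-axis of an unfiltered graph."""
        return np.arange(1, self.values.size + 1)

    def with_values(self, values: np.ndarray, **changes) -> "BreathSeries":
        """Copy of this series with new values (and optional field changes)."""
        return replace(self, values=np.asarray(values, dtype=float), **changes)

    def __len__(self) -> int:
        return self.n_cycles


def _check_contiguous(labels: np.ndarray) -> None:
    """Each distinct label must form exactly one contiguous run."""
    seen: set = set()
    prev = None
    for lab in labels:
        if lab != prev:
            if lab in seen:
                raise ValueError(
                    f"phase label {lab!r} appears in more than one block"
                )
            seen.add(lab)
            prev = lab
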