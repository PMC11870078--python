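"""Reading and writing breath-by-breath series as delimited text.

CPET software exports one row per respiratory cycle.  Vendors differ in
delimiter (comma, semicolon or tab) and European exports often use a
decimal comma; both are auto-detected.  Lines starting with ``#`` are
provenance/comment lines and are skipped.

Expected columns (case-insensitive, synonyms accepted):

- ``cycle`` — 1-based, strictly increasing cycle index (required)
- ``vt_ml`` / ``vt`` — tidal volume, mL
- ``bf_per_min`` / ``bf`` — breathing frequency, breaths/min
- ``phase`` — optional phase label (rest/warmup/exercise/recovery)
- ``is_sigh`` — optional 0/1 flag
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .series import BreathSeries, ParameterKind

__all__ = ["read_breath_csv", "write_series_csv", "FormatError",
           "provenance_header"]

logger = logging.getLogger(__name__)

_COLUMN_SYNONYMS = {
    "cycle": "cycle", "cycle_index": "cycle", "breath": "cycle",
    "vt": "vt", "vt_ml": "vt", "tidal_volume": "vt",
    "bf": "bf", "bf_per_min": "bf", "breathing_frequency": "bf",
    "phase": "phase",
    "is_sigh": "is_sigh", "sigh": "is_sigh",
}

_DELIMITERS = (",", ";", "\t")


class FormatError(ValueError):
    """Malformed breath CSV; the message carries the offending line number."""


def _sniff_delimiter(header_line: str) -> str:
    counts = {d: header_line.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    if counts[best] == 0:
        raise FormatError("no recognised delimiter (comma/semicolon/tab) in header")
    return best


def _parse_number(token: str, delimiter: str, line_no: int) -> float:
    token = token.strip()
    if delimiter != "," and "," in token and "." not in token:
        token = token.replace(",", ".")  # decimal comma
    try:
        return float(token)
    except ValueError:
        raise FormatError(f"line {line_no}: cannot parse number {token!r}") from None


def read_breath_csv(path, parameter: ParameterKind | str = ParameterKind.VT_ML
                    ) -> BreathSeries:
    """Read one breathing parameter from a delimited text file.

    Rows with a missing value for the selected parameter raise a
    :class:`FormatError` naming the rows.  Cycle indices must be
    strictly increasing (1-based; no silent reindexing).
    """
    parameter = ParameterKind(parameter)
    want = "vt" if parameter is ParameterKind.VT_ML else "bf"
    path = Path(path)
    lines = [
        (no, line.rstrip("\n"))
        for no, line in enumerate(path.read_text().splitlines(), start=1)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: no data lines")
    header_no, header_line = lines[0]
    delimiter = _sniff_delimiter(header_line)
    raw_names = [c.strip().lower() for c in header_line.split(delimiter)]
    if any(_looks_numeric(c) for c in raw_names):
        raise FormatError(f"line {header_no}: missing header row")
    columns = {}
    for pos, name in enumerate(raw_names):
        canon = _COLUMN_SYNONYMS.get(name)
        if canon is not None and canon not in columns:
            columns[canon] = pos
    if "cycle" not in columns:
        raise FormatError(f"line {header_no}: no 'cycle' column")
    if want not in columns:
        # a generic 'value' column (our own simulate output) serves either
        if "value" in raw_names:
            columns[want] = raw_names.index("value")
        else:
            raise FormatError(
                f"line {header_no}: no column for parameter {parameter.value!r}"
            )

    cycles, values, phase_labels, sigh_cycles = [], [], [], []
    missing_rows = []
    for no, line in lines[1:]:
        fields = line.split(delimiter)
        token = fields[columns[want]].strip() if columns[want] < len(fields) else ""
        if token == "" or token.upper() in ("NA", "NAN"):
            missing_rows.append(no)
            continue
        cyc = int(_parse_number(fields[columns["cycle"]], delimiter, no))
        if cycles and cyc <= cycles[-1]:
            raise FormatError(f"line {no}: cycle index {cyc} not increasing")
        cycles.append(cyc)
        values.append(_parse_number(token, delimiter, no))
        if "phase" in columns and columns["phase"] < len(fields):
            phase_labels.append(fields[columns["phase"]].strip().lower())
        if "is_sigh" in columns and columns["is_sigh"] < len(fields):
            if fields[columns["is_sigh"]].strip() in ("1", "true", "True"):
                sigh_cycles.append(cyc)
    if missing_rows:
        raise FormatError(
            f"missing {parameter.value!r} values on lines {missing_rows}"
        )
    if not values:
        raise FormatError(f"{path}: empty selection for {parameter.value!r}")

    if parameter is ParameterKind.VT_ML and np.median(values) < 15:
        logger.warning(
            "median VT %.3g looks like litres; expected mL", np.median(values)
        )
    return BreathSeries(
        np.asarray(values),
        parameter,
        phase_labels=np.asarray(phase_labels, dtype=object) if phase_labels else None,
        sigh_positions=np.asarray(sigh_cycles, dtype=int) if sigh_cycles else None,
    )


def _looks_numeric(token: str) -> bool:
    try:
        float(token.replace(",", "."))
        return True
    except ValueError:
        return False


def provenance_header(seed=None, config: dict | None = None) -> str:
    """Comment line recording tool version, seed and a config digest."""
    digest = hashlib.sha1(
        json.dumps(config or {}, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return f"# breathvar {__version__} | seed={seed} | config={digest}"


def write_series_csv(path, series: BreathSeries, seed=None,
                     config: dict | None = None) -> None:
    """Write a series as ``cycle,value,is_sigh[,phase]`` with provenance."""
    sighs = set(map(int, series.sigh_positions)) if series.sigh_positions is not None else set()
    cols = ["cycle", "value", "is_sigh"]
    if series.phase_labels is not None:
        cols.append("phase")
    out = [provenance_header(seed=seed, config=config), ",".join(cols)]
    for i, v in enumerate(series.values, start=1):
        row = [str(i), repr(float(v)), "1" if i in sighs else "0"]
        if series.phase_labels is not None:
            row.append(str(series.phase_labels[i - 1]))
        out.append(",".join(row))
    Path(path).write_text("\n".join(out) + "\n")
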