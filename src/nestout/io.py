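"""Readers for the two raw dataset layouts used in smartphone HAR studies.

Two dialects are supported: raw accelerometer CSV in the WISDM style
(``user,activity,timestamp,x,y,z`` with a trailing ``;`` per line), and
already-processed fixed-width feature tables in the UCI-HAR style (hundreds
of attributes per row plus a numeric activity label).  Raw input is cleaned,
never rejected: blank or malformed lines and exact duplicates are dropped
and counted in a :class:`CleaningReport`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import LabeledStream

__all__ = [
    "CleaningReport",
    "ProcessedTable",
    "read_wisdm_raw",
    "stream_from_records",
    "read_processed_table",
]

RAW_COLUMNS = ("user", "activity", "timestamp", "x", "y", "z")


@dataclass(frozen=True)
class CleaningReport:
    """Counts from cleaning a raw file: dropped rows by reason, rows kept."""

    n_blank_or_malformed: int
    n_duplicates: int
    n_kept: int


def _parse_raw_line(line: str) -> tuple[str, ...] | None:
    """Normalize one raw line; return 6 fields or None if malformed.

    Malformed covers blank lines, field counts other than 6 (which also
    catches duplicated columns and stray separators), and non-numeric
    user/timestamp/acceleration fields.
    """
    s = line.strip()
    if s.endswith(";"):
        s = s[:-1].strip()
    if not s:
        return None
    parts = [p.strip() for p in s.split(",")]
    if len(parts) != 6:
        return None
    user, activity, timestamp, x, y, z = parts
    if not activity or any(not p for p in parts):
        return None
    try:
        int(user)
        int(timestamp)
        float(x), float(y), float(z)
    except ValueError:
        return None
    return tuple(parts)


def read_wisdm_raw(text_lines: Iterable[str]) -> tuple[pd.DataFrame, CleaningReport]:
    """Parse and clean WISDM-dialect raw lines.

    Returns the kept records as a DataFrame with columns
    ``user, activity, timestamp, x, y, z`` and a :class:`CleaningReport`.
    Duplicates are exact field-level matches after separator normalisation;
    the first occurrence is kept.
    """
    seen: set[tuple[str, ...]] = set()
    kept: list[tuple[str, ...]] = []
    n_bad = 0
    n_dup = 0
    for line in text_lines:
        parsed = _parse_raw_line(line)
        if parsed is None:
            n_bad += 1
            continue
        if parsed in seen:
            n_dup += 1
            continue
        seen.add(parsed)
        kept.append(parsed)

    frame = pd.DataFrame(kept, columns=list(RAW_COLUMNS))
    if len(frame):
        frame = frame.astype(
            {"user": np.int64, "timestamp": np.int64,
             "x": float, "y": float, "z": float}
        )
    report = CleaningReport(
        n_blank_or_malformed=n_bad, n_duplicates=n_dup, n_kept=len(kept)
    )
    return frame, report


def stream_from_records(records: pd.DataFrame) -> LabeledStream:
    """Assemble cleaned raw records into a labelled stream.

    Records are ordered by (user, timestamp); timestamps are converted from
    nanoseconds to seconds since the first sample.
    """
    if records.empty:
        raise ValueError("no records to assemble into a stream")
    ordered = records.sort_values(["user", "timestamp"], kind="stable")
    ts = ordered["timestamp"].to_numpy(dtype=float)
    t = (ts - ts[0]) / 1e9
    # Guard against duplicate timestamps across users: fall back to uniform
    # spacing at the median interval if the concatenation is not increasing.
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        dt = float(np.median(np.abs(np.diff(t)))) or 1.0
        t = np.arange(len(t)) * dt
    channels = ordered[["x", "y", "z"]].to_numpy(dtype=float)
    labels = ordered["activity"].to_numpy(dtype=object)
    return LabeledStream(t, channels, labels)


@dataclass
class ProcessedTable:
    """Fixed-width feature table with textual activity labels."""

    features: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")


def read_processed_table(
    rows: Iterable[Sequence | str],
    label_map: Mapping[int, str],
) -> ProcessedTable:
    """Load a processed feature table whose last column is a numeric label.

    ``rows`` may be sequences of numbers or whitespace-delimited strings.
    Numeric labels are replaced by text through ``label_map``; row width
    must be constant.  An unmapped label or a ragged row is an error (the
    ragged-row error names the offending row index).
    """
    feats: list[list[float]] = []
    labels: list[str] = []
    width: int | None = None
    for i, row in enumerate(rows):
        if isinstance(row, str):
            row = row.split()
        values = [float(v) for v in row]
        if width is None:
            width = len(values)
            if width < 2:
                raise ValueError("rows need at least one feature and a label")
        elif len(values) != width:
            raise ValueError(
                f"ragged row {i}: expected {width} columns, got {len(values)}"
            )
        raw_label = values[-1]
        key = int(raw_label)
        if key != raw_label or key not in label_map:
            raise ValueError(f"row {i}: unmapped activity label {raw_label!r}")
        feats.append(values[:-1])
        labels.append(label_map[key])

    n_feat = (width - 1) if width else 0
    frame = pd.DataFrame(feats, columns=[f"attr{j}" for j in range(n_feat)])
    return ProcessedTable(frame, pd.Series(labels, dtype=object, name="label"))
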