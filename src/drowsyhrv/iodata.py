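"""Readers and writers for inter-beat-interval streams and feature tables.

Two interval dialects are supported:

* wristband exports: first line is the session start epoch, every
  following line is ``offset_seconds,duration_seconds`` (one beat per row);
* ECG RR text: one RR interval in milliseconds per line, beat times
  reconstructed as the cumulative sum starting at 0.

Both produce an :class:`IBISeries` that is validated on construction;
corrupt files raise instead of being silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

WRISTBAND = "wristband"
ECG = "ecg"
_DEVICES = (WRISTBAND, ECG)

#: gap between successive beats (s) above which a dropout is flagged
DROPOUT_GAP_S = 3.0


class ParseError(ValueError):
    """A line of an interval file could not be parsed."""


class ValidationError(ValueError):
    """Parsed data violates an IBISeries invariant."""


@dataclass
class IBISeries:
    """One subject/device stream of beat times and beat-to-beat intervals.

    beat_times are seconds from session start (strictly increasing);
    intervals are milliseconds, one per beat after the first, and must
    agree with the beat-time differences to 1 ms.
    """

    subject_id: str
    device: str
    beat_times: np.ndarray
    intervals: np.ndarray
    session_start: float | None = None
    dropout_gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.device not in _DEVICES:
            raise ValidationError(f"unknown device {self.device!r}; expected one of {_DEVICES}")
        if self.intervals.size != max(self.beat_times.size - 1, 0):
            raise ValidationError(
                f"expected {max(self.beat_times.size - 1, 0)} intervals for "
                f"{self.beat_times.size} beats, got {self.intervals.size}"
            )
        if self.beat_times.size > 1:
            diffs = np.diff(self.beat_times)
            if np.any(diffs <= 0):
                i = int(np.argmax(diffs <= 0))
                raise ValidationError(f"beat_times not strictly increasing at index {i + 1}")
            if np.any(self.intervals <= 0):
                raise ValidationError("all intervals must be > 0")
            if np.any(np.abs(diffs * 1000.0 - self.intervals) > 1.0):
                i = int(np.argmax(np.abs(diffs * 1000.0 - self.intervals) > 1.0))
                raise ValidationError(
                    f"interval {i} ({self.intervals[i]} ms) disagrees with beat-time "
                    f"difference ({diffs[i] * 1000.0:.3f} ms) by more than 1 ms"
                )
            self.dropout_gaps = [
                (float(self.beat_times[i]), float(self.beat_times[i + 1]))
                for i in np.nonzero(diffs > DROPOUT_GAP_S)[0]
            ]

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    @property
    def duration(self) -> float:
        """Recording span in seconds (time of last beat)."""
        return float(self.beat_times[-1]) if self.beat_times.size else 0.0


def read_empatica_ibi(path: str | Path, subject_id: str = "") -> IBISeries:
    """Read a wristband-style IBI export.

    First line: session start epoch (anything before an optional comma).
    Each following line: ``offset_seconds,duration_seconds``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file, missing session-start header")
    header = lines[0].split(",")[0].strip()
    try:
        session_start = float(header)
    except ValueError as exc:
        raise ParseError(f"{path}:1: malformed session-start header {lines[0]!r}") from exc

    times, durations = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'offset,duration', got {line!r}")
        try:
            t, d = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field in {line!r}") from exc
        times.append(t)
        durations.append(d)

    times_arr = np.asarray(times, dtype=float)
    if times_arr.size > 1 and np.any(np.diff(times_arr) <= 0):
        i = int(np.argmax(np.diff(times_arr) <= 0))
        raise ValidationError(f"{path}: non-increasing beat offsets at rows {i + 2}-{i + 3}")
    intervals = np.asarray(durations[1:], dtype=float) * 1000.0
    return IBISeries(
        subject_id=subject_id or path.stem,
        device=WRISTBAND,
        beat_times=times_arr,
        intervals=intervals,
        session_start=session_start,
    )


def read_rr_text(path: str | Path, device: str, subject_id: str = "") -> IBISeries:
    """Read plain RR-interval text: one interval in ms per line.

    Beat times are the cumulative interval sums in seconds, starting at 0.
    """
    path = Path(path)
    rr = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            v = float(line)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric RR value {line!r}") from exc
        if v <= 0:
            raise ValidationError(f"{path}:{lineno}: non-positive RR interval {v}")
        rr.append(v)
    rr_arr = np.asarray(rr, dtype=float)
    beat_times = np.concatenate([[0.0], np.cumsum(rr_arr) / 1000.0])
    return IBISeries(
        subject_id=subject_id or path.stem,
        device=device,
        beat_times=beat_times,
        intervals=rr_arr,
        session_start=None,
    )


def write_ibi_files(series: IBISeries, directory: str | Path) -> Path:
    """Write a series back to its native dialect under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if series.device == WRISTBAND:
        out = directory / f"{series.subject_id}_wristband_ibi.csv"
        lines = [f"{series.session_start if series.session_start is not None else 0.0}"]
        # the first beat has no preceding interval; convention: repeat the first one
        first = series.intervals[0] / 1000.0 if series.intervals.size else 0.0
        durations = np.concatenate([[first], series.intervals / 1000.0])
        for t, d in zip(series.beat_times, durations):
            lines.append(f"{t:.6f},{d:.6f}")
        out.write_text("\n".join(lines) + "\n")
    else:
        out = directory / f"{series.subject_id}_ecg_rr.txt"
        out.write_text("\n".join(f"{v:.6f}" for v in series.intervals) + "\n")
    return out


# fixed header of the labeled feature table
FEATURE_TABLE_META = ["subject", "device", "window_start_s"]
FEATURE_TABLE_TAIL = ["level", "binary_class"]


def write_feature_table(path: str | Path, rows: pd.DataFrame) -> None:
    """Write labeled feature windows as delimited text (CSV).

    Column order must be: subject, device, window_start_s, the 26 feature
    names, level, binary_class. Round-trips losslessly through
    :func:`read_feature_table`.
    """
    cols = list(rows.columns)
    if cols[:3] != FEATURE_TABLE_META or cols[-2:] != FEATURE_TABLE_TAIL:
        raise ValidationError(
            "feature table must start with "
            f"{FEATURE_TABLE_META} and end with {FEATURE_TABLE_TAIL}; got {cols[:3]} ... {cols[-2:]}"
        )
    if len(set(cols)) != len(cols):
        raise ValidationError("duplicate column names in feature table")
    rows.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:3] != FEATURE_TABLE_META or cols[-2:] != FEATURE_TABLE_TAIL:
        raise ValidationError(f"{path}: not a feature table (unexpected columns {cols[:3]})")
    return df
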