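"""Drowsiness ground-truth construction.

Observer ratings (6-level scale, one joint rating per 5-min interval of a
45-min drive) are combined with micro-sleep events detected from video.
An eyelid closure of at least 1 s maps directly onto scale levels 4-6 by
its duration; intervals containing such events have their rating replaced
by the level derived from the longest closure in that interval — the
replacement can lower a rating as well as raise it. Levels 1-3 form the
"non-drowsy" class, levels 4-6 the "drowsy" class.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np

NON_DROWSY = "non_drowsy"
DROWSY = "drowsy"

N_INTERVALS = 9
INTERVAL_LENGTH_S = 300.0

#: eyelid-closure duration bins (s) mapping to drowsiness levels.
#: Closures of 3-4 s fall outside the rating scale's own wording
#: (level 5: 2-3 s, level 6: >= 4 s) and are assigned to level 5.
MICROSLEEP_BINS = ((1.0, 2.0, 4), (2.0, 4.0, 5), (4.0, float("inf"), 6))


@dataclass(frozen=True)
class RatingRecord:
    subject_id: str
    interval_index: int
    level: int | None
    rater_id: str = "joint"

    def __post_init__(self) -> None:
        if not 0 <= self.interval_index <= N_INTERVALS - 1:
            raise ValueError(f"interval_index {self.interval_index} outside 0..{N_INTERVALS - 1}")
        if self.level is not None and not 1 <= self.level <= 6:
            raise ValueError(f"rating level {self.level} outside 1..6")


@dataclass(frozen=True)
class MicroSleepEvent:
    subject_id: str
    onset_time: float
    closure_duration: float

    def __post_init__(self) -> None:
        if self.closure_duration < 1.0:
            raise ValueError(
                f"closure_duration {self.closure_duration} < 1 s is not a micro-sleep event"
            )
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")

    @property
    def interval_index(self) -> int:
        return int(self.onset_time // INTERVAL_LENGTH_S)


@dataclass(frozen=True)
class IntervalLabel:
    subject_id: str
    interval_index: int
    level: int
    provenance: str = "observer"  # observer | adjusted | microsleep_only

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 6:
            raise ValueError(f"level {self.level} outside 1..6")

    @property
    def binary_class(self) -> str:
        return binarize(self.level)


@dataclass(frozen=True)
class AgreementStats:
    n_items: int
    n_agree: int
    percent_agreement: float
    kappa: float


def categorize_microsleep(closure_duration: float) -> int | None:
    """Map an eyelid-closure duration (s) to a drowsiness level 4-6.

    Durations below 1 s are not micro-sleep events and return None.
    """
    if closure_duration < 0:
        raise ValueError(f"negative closure duration {closure_duration}")
    for lo, hi, level in MICROSLEEP_BINS:
        if lo <= closure_duration < hi:
            return level
    return None


def binarize(level: int) -> str:
    """Group levels 1-3 as non-drowsy, 4-6 as drowsy."""
    if not 1 <= int(level) <= 6 or int(level) != level:
        raise ValueError(f"level {level} outside the 1..6 scale")
    return NON_DROWSY if level <= 3 else DROWSY


def adjust_ratings(
    ratings: list[RatingRecord], events: list[MicroSleepEvent]
) -> list[IntervalLabel]:
    """Combine joint observer ratings with micro-sleep events.

    For every (subject, interval) with at least one event, the label level
    becomes the level derived from the *longest* closure in that interval,
    replacing the observer level (possibly lowering it). Intervals with
    events but no rating gain a new label; intervals with neither are
    absent from the output.
    """
    by_key: dict[tuple[str, int], int] = {}
    for r in ratings:
        key = (r.subject_id, r.interval_index)
        if key in by_key:
            raise ValueError(f"duplicate joint rating for subject {r.subject_id} "
                             f"interval {r.interval_index}")
        if r.level is None:
            raise ValueError("joint ratings must carry a level")
        by_key[key] = r.level

    longest: dict[tuple[str, int], float] = defaultdict(float)
    for e in events:
        idx = e.interval_index
        if idx > N_INTERVALS - 1:
            raise ValueError(
                f"event at {e.onset_time} s maps to interval {idx}, outside the drive"
            )
        key = (e.subject_id, idx)
        longest[key] = max(longest[key], e.closure_duration)

    labels: list[IntervalLabel] = []
    for key, level in by_key.items():
        subject, idx = key
        if key in longest:
            new_level = categorize_microsleep(longest[key])
            assert new_level is not None
            prov = "adjusted" if new_level != level else "observer"
            labels.append(IntervalLabel(subject, idx, new_level, prov))
        else:
            labels.append(IntervalLabel(subject, idx, level, "observer"))
    for key in sorted(set(longest) - set(by_key)):
        subject, idx = key
        new_level = categorize_microsleep(longest[key])
        assert new_level is not None
        labels.append(IntervalLabel(subject, idx, new_level, "microsleep_only"))
    return labels


def agreement_stats(ratings_a: list[int], ratings_b: list[int]) -> AgreementStats:
    """Percent agreement and Cohen's kappa for two raters over common items.

    kappa = (p_o - p_e) / (1 - p_e), with expected agreement p_e from the
    two raters' marginal level frequencies.
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError(f"length mismatch: {len(ratings_a)} vs {len(ratings_b)}")
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    n = a.size
    if n == 0:
        raise ValueError("no items to compare")
    n_agree = int(np.sum(a == b))
    p_o = n_agree / n
    levels = np.union1d(a, b)
    p_e = sum((np.mean(a == lv)) * (np.mean(b == lv)) for lv in levels)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AgreementStats(
        n_items=n,
        n_agree=n_agree,
        percent_agreement=100.0 * n_agree / n,
        kappa=float(kappa),
    )


def class_counts(labels: list[IntervalLabel]) -> tuple[int, int]:
    """(n_non_drowsy, n_drowsy) over a label list."""
    n_drowsy = sum(1 for l in labels if l.binary_class == DROWSY)
    return len(labels) - n_drowsy, n_drowsy
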