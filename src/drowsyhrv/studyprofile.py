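"""Published annotation statistics of the 30-subject simulator study.

The driving-simulator study this pipeline was designed around published
its annotation bookkeeping as summary tables: the class distribution of
the 244 usable joint video ratings, the 10 distinct rating adjustments
triggered by micro-sleep events (21 changed ratings plus 2 intervals that
gained a rating), the duration histogram of the 201 detected micro-sleep
events, and the raw two-rater agreement (191 of 244 decisions identical).
Those printed numbers are inputs here: this module encodes them and can
materialise a synthetic annotation set that realises them exactly, so the
ground-truth arithmetic can be exercised end to end without the original
recordings.
"""

from __future__ import annotations

import itertools

from .ground_truth import MicroSleepEvent, RatingRecord, INTERVAL_LENGTH_S

#: (observer level or None, adjusted level, occurrences) — the published
#: adjustment table; None marks intervals without an observer rating.
ADJUSTMENT_TRANSITIONS: list[tuple[int | None, int, int]] = [
    (1, 4, 1),
    (2, 4, 3),
    (2, 5, 4),
    (2, 6, 1),
    (3, 4, 2),
    (3, 5, 5),
    (4, 5, 3),
    (5, 6, 1),
    (6, 4, 1),
    (None, 6, 2),
]

#: published pre-adjustment class counts of the 244 joint ratings
RATING_CLASS_COUNTS_BEFORE = (212, 32)
#: and after integrating micro-sleep events (246 ratings total)
RATING_CLASS_COUNTS_AFTER = (196, 50)

#: micro-sleep duration histogram: level -> event count (total 201)
MICROSLEEP_EVENT_COUNTS = {4: 89, 5: 69, 6: 43}

#: identical rater decisions / paired items
RATER_AGREEMENT = (191, 244)

N_SUBJECTS = 30

#: a closure duration strictly inside the bin that maps to each level
_REPRESENTATIVE_CLOSURE = {4: 1.5, 5: 2.5, 6: 4.5}


def build_annotation_tables() -> tuple[list[RatingRecord], list[MicroSleepEvent]]:
    """Materialise ratings and events realising the published tables.

    Returns 244 joint ratings whose binary class counts equal
    RATING_CLASS_COUNTS_BEFORE, plus one micro-sleep event per adjusted
    interval such that applying the adjustment rule reproduces every
    ADJUSTMENT_TRANSITIONS row and hence RATING_CLASS_COUNTS_AFTER.
    """
    slot_iter = iter(
        (f"s{subj:02d}", interval)
        for subj in range(1, N_SUBJECTS + 1)
        for interval in range(9)
    )

    ratings: list[RatingRecord] = []
    events: list[MicroSleepEvent] = []

    def add_event(subject: str, interval: int, level: int) -> None:
        onset = interval * INTERVAL_LENGTH_S + 10.0
        events.append(MicroSleepEvent(subject, onset, _REPRESENTATIVE_CLOSURE[level]))

    # intervals realising each published adjustment row
    for observer, adjusted, count in ADJUSTMENT_TRANSITIONS:
        for _ in range(count):
            subject, interval = next(slot_iter)
            if observer is not None:
                ratings.append(RatingRecord(subject, interval, observer))
            add_event(subject, interval, adjusted)

    # remaining untouched ratings fill the published pre-adjustment counts
    n_adj_nd = sum(c for obs, _, c in ADJUSTMENT_TRANSITIONS if obs is not None and obs <= 3)
    n_adj_d = sum(c for obs, _, c in ADJUSTMENT_TRANSITIONS if obs is not None and obs >= 4)
    for level, remaining in ((2, RATING_CLASS_COUNTS_BEFORE[0] - n_adj_nd),
                             (4, RATING_CLASS_COUNTS_BEFORE[1] - n_adj_d)):
        for _ in range(remaining):
            subject, interval = next(slot_iter)
            ratings.append(RatingRecord(subject, interval, level))

    return ratings, events


def build_microsleep_durations() -> list[float]:
    """201 closure durations matching the published duration histogram,
    including both bin boundaries (1, 2, 4 s) and the 3-4 s closures that
    the scale's own wording leaves unassigned (allocated to level 5)."""
    durations: list[float] = []
    fillers = {4: [1.0, 1.5, 1.9], 5: [2.0, 2.5, 3.5, 3.99], 6: [4.0, 4.5, 8.0]}
    for level, count in MICROSLEEP_EVENT_COUNTS.items():
        pool = itertools.cycle(fillers[level])
        durations.extend(next(pool) for _ in range(count))
    return durations


def build_rater_decisions() -> tuple[list[int], list[int]]:
    """Two level lists of length 244 with exactly 191 identical decisions."""
    n_agree, n_items = RATER_AGREEMENT
    a = [(i % 6) + 1 for i in range(n_items)]
    b = list(a)
    for i in range(n_items - n_agree):
        b[i] = (a[i] % 6) + 1  # shift disagreeing items one level up (wrapping)
    return a, b
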