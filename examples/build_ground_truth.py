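"""Build drowsiness labels from observer ratings and micro-sleep events.

Reproduces the published annotation bookkeeping of the 30-subject
simulator study this pipeline emulates: 244 joint video ratings
(212 non-drowsy / 32 drowsy) are adjusted by micro-sleep events —
eyelid closures of 1-2 s map to level 4, 2-4 s to level 5, >= 4 s to
level 6, and an interval's rating is replaced by the level of its
longest closure — yielding 246 labels split 196 / 50.
"""

from drowsyhrv import adjust_ratings, agreement_stats, class_counts
from drowsyhrv.studyprofile import (
    build_annotation_tables,
    build_rater_decisions,
)

ratings, events = build_annotation_tables()
print(f"joint observer ratings: {len(ratings)}")
print(f"event-bearing adjustments: {len(events)} intervals")

before = class_counts(adjust_ratings(ratings, []))
labels = adjust_ratings(ratings, events)
after = class_counts(labels)
print(f"class counts before adjustment (non-drowsy, drowsy): {before}")
print(f"class counts after adjustment:  {after}, total {len(labels)}")

a, b = build_rater_decisions()
stats = agreement_stats(a, b)
print(f"raw two-rater agreement: {stats.n_agree}/{stats.n_items} "
      f"= {stats.percent_agreement:.2f}%")

# The drowsy class grows from 32 to 50 because most adjustments move
# ratings upward; one closure-derived correction moves a rating down.
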