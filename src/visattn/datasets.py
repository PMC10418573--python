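"""Reference cohort data for worked examples and validation.

Per-image correct/incorrect judgment counts from a published eye-tracking
study in which 22 geneticist clinicians and 22 non-clinicians each viewed
16 standardized facial images (10 genetic conditions, 6 unaffected) for
seven seconds and judged whether the person shown was affected. Seven
isolated eye-tracking results were discarded for technical reasons, so not
every image has complete data from all 44 participants.

Rows are in presentation order. The third count per group is how many
participants also named the specific condition correctly (descriptive only).
"""

from __future__ import annotations

import numpy as np

from .stats import ContingencyTable

# stimulus, clin_correct, clin_incorrect, clin_named, non_correct, non_incorrect, non_named
STUDY_RESPONSE_COUNTS: list[tuple[str, int, int, int, int, int, int]] = [
    ("WS",           17,  5,  4, 13,  9, 3),
    ("Unaffected-1", 22,  0,  0, 19,  3, 0),
    ("RSTS1",        21,  0,  3, 21,  1, 0),
    ("Unaffected-2", 19,  3,  0, 14,  8, 0),
    ("WHS",          20,  2,  0, 19,  3, 0),
    ("Unaffected-3", 22,  0,  0, 20,  2, 0),
    ("CdLS",         22,  0, 10, 22,  0, 5),
    ("DS",           22,  0, 18, 21,  1, 1),
    ("Unaffected-4", 15,  6,  0, 15,  6, 0),
    ("KS",           19,  3, 11, 13,  9, 2),
    ("NS",           21,  0,  9, 21,  0, 0),
    ("Unaffected-5", 18,  4,  0, 18,  4, 0),
    ("22q11DS",      21,  1,  3, 19,  3, 0),
    ("PWS",          16,  5,  0, 10, 12, 0),
    ("Unaffected-6", 14,  8,  0, 19,  3, 0),
    ("BWS",           8, 13,  1,  5, 17, 0),
]


def study_contingency_table() -> ContingencyTable:
    """Summed 2×2 table over all 16 images: group × (correct, incorrect)."""
    arr = np.array([[r[1], r[2]] for r in STUDY_RESPONSE_COUNTS]).sum(axis=0)
    non = np.array([[r[4], r[5]] for r in STUDY_RESPONSE_COUNTS]).sum(axis=0)
    return ContingencyTable(np.stack([arr, non]))
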