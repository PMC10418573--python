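"""Cohort accuracy analysis and AOI fixation-timing metrics.

Accuracy of affected/unaffected judgments is summarized per participant
group in a 2×2 contingency table (group × correct/incorrect) and tested
with an uncorrected Pearson chi-square (df = 1). No Yates continuity
correction is applied — the uncorrected statistic is the appropriate test
at these cell counts and is what the accuracy analysis reports.

AOI metrics reduce a fixation sequence against analyst-drawn polygons to
duration-of-fixation (total dwell time inside the AOI) and
time-to-first-whole-fixation (onset of the earliest fixation inside).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from shapely.geometry import Point
from shapely import prepared

from .gaze_io import AOISet, FixationSequence, Group

logger = logging.getLogger(__name__)

Truth = Literal["affected", "unaffected"]


@dataclass(frozen=True)
class ResponseRecord:
    """One participant's judgment of one stimulus."""

    participant_id: str
    group: Group
    stimulus_id: str
    truth: str  # affected | unaffected
    judgment: str  # affected | unaffected | missing
    named_condition: str | None = None

    @property
    def is_missing(self) -> bool:
        return self.judgment == "missing"

    @property
    def is_correct(self) -> bool:
        if self.is_missing:
            raise ValueError("missing judgment has no correctness")
        return self.judgment == self.truth


@dataclass
class ContingencyTable:
    """2×2 counts: rows = (clinician, non_clinician), cols = (correct, incorrect)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("contingency table must be 2×2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def clinician(self) -> tuple[int, int]:
        return tuple(self.counts[0])

    @property
    def non_clinician(self) -> tuple[int, int]:
        return tuple(self.counts[1])


def build_contingency(responses: Iterable[ResponseRecord]) -> ContingencyTable:
    """Tally correct/incorrect judgments per group; missing responses dropped.

    A judgment is correct iff it equals the stimulus truth. Coverage may be
    incomplete (discarded eye-tracking results leave holes); the number of
    missing responses is logged.
    """
    counts = np.zeros((2, 2), dtype=np.int64)
    row = {Group.CLINICIAN: 0, Group.NON_CLINICIAN: 1}
    n_missing = 0
    n_total = 0
    for r in responses:
        n_total += 1
        if r.is_missing:
            n_missing += 1
            continue
        counts[row[Group(r.group)], 0 if r.is_correct else 1] += 1
    if n_total == n_missing:
        raise ValueError("no non-missing responses to tally")
    if n_missing:
        logger.info("dropped %d missing responses of %d", n_missing, n_total)
    return ContingencyTable(counts)


def accuracy(table: ContingencyTable) -> dict[str, float]:
    """Per-group percent correct, rounded to one decimal."""
    out = {}
    for grp, (correct, incorrect) in (
        ("clinician", table.clinician),
        ("non_clinician", table.non_clinician),
    ):
        total = correct + incorrect
        if total == 0:
            raise ValueError(f"no responses for group {grp}")
        out[grp] = float(round(100.0 * correct / total, 1))
    return out


def chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on the 2×2 table; returns (statistic, p)."""
    if np.any(table.counts.sum(axis=0) == 0) or np.any(table.counts.sum(axis=1) == 0):
        raise ValueError("chi-square requires positive row and column margins")
    stat, p, dof, _ = sps.chi2_contingency(table.counts, correction=False)
    assert dof == 1
    return float(stat), float(p)


@dataclass
class AOIMetrics:
    """One participant's dwell metrics on one AOI."""

    stimulus_id: str
    aoi_name: str
    participant_id: str
    duration_of_fixation_ms: float
    time_to_first_whole_fixation_ms: float | None  # None when never fixated


def aoi_metrics(seq: FixationSequence, aois: AOISet) -> list[AOIMetrics]:
    """Dwell time and first-entry latency of a sequence on each AOI.

    A fixation counts as inside an AOI iff its center point lies inside or
    on the polygon boundary (boundary-inclusive, even-odd rule).
    duration-of-fixation sums the durations of inside-fixations;
    time-to-first-whole-fixation is the onset of the earliest one, or absent
    if the AOI was never fixated.
    """
    if seq.stimulus_id != aois.stimulus_id:
        raise ValueError(
            f"stimulus mismatch: sequence is {seq.stimulus_id!r}, AOIs are {aois.stimulus_id!r}"
        )
    out: list[AOIMetrics] = []
    for name, poly in aois.aois:
        prep = prepared.prep(poly)
        duration = 0.0
        first: float | None = None
        for f in seq.fixations:  # already onset-sorted
            pt = Point(f.x_px, f.y_px)
            if prep.intersects(pt):  # covers interior and boundary
                duration += f.duration_ms
                if first is None:
                    first = f.onset_ms
        out.append(
            AOIMetrics(
                stimulus_id=seq.stimulus_id,
                aoi_name=name,
                participant_id=seq.participant_id,
                duration_of_fixation_ms=duration,
                time_to_first_whole_fixation_ms=first,
            )
        )
    return out


def aoi_metrics_table(
    sequences: Sequence[FixationSequence], aoi_sets: dict[str, AOISet]
) -> pd.DataFrame:
    """Tidy AOI metrics: one row per participant × stimulus × AOI."""
    rows = []
    for seq in sequences:
        aois = aoi_sets.get(seq.stimulus_id)
        if aois is None:
            continue
        for m in aoi_metrics(seq, aois):
            rows.append(
                {
                    "participant_id": m.participant_id,
                    "group": seq.group.value,
                    "stimulus_id": m.stimulus_id,
                    "aoi_name": m.aoi_name,
                    "duration_of_fixation_ms": m.duration_of_fixation_ms,
                    "time_to_first_whole_fixation_ms": m.time_to_first_whole_fixation_ms,
                }
            )
    return pd.DataFrame(rows)


def read_response_table(source) -> list[ResponseRecord]:
    """Parse a responses TSV: participant_id, group, stimulus_id, truth,
    judgment, named_condition (optional)."""
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    required = ["participant_id", "group", "stimulus_id", "truth", "judgment"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing column(s): {', '.join(missing)}")
    records = []
    for r in df.itertuples():
        named = getattr(r, "named_condition", None)
        if named is not None and (pd.isna(named) or named == ""):
            named = None
        records.append(
            ResponseRecord(
                participant_id=str(r.participant_id),
                group=Group(r.group),
                stimulus_id=str(r.stimulus_id),
                truth=str(r.truth),
                judgment=str(r.judgment),
                named_condition=named,
            )
        )
    return records


def write_response_table(responses: Sequence[ResponseRecord], dest) -> None:
    df = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group": Group(r.group).value,
                "stimulus_id": r.stimulus_id,
                "truth": r.truth,
                "judgment": r.judgment,
                "named_condition": r.named_condition or "",
            }
            for r in responses
        ]
    )
    df.to_csv(dest, sep="\t", index=False)
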