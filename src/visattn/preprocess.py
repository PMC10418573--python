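"""Common-attention subtraction pipeline for group heat maps.

Raw group-average heat maps of faces are dominated by generic face-viewing
behavior — everyone looks at the eyes, nose and mouth. To expose what a
group looked at *beyond* that, we estimate each group's common attention
pattern (the average of its per-stimulus average maps over all stimuli) and
subtract it from each per-stimulus average, clipping negatives to zero. The
residual maps are what the thresholded IoU comparisons operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .gaze_io import AttentionMap, FixationSequence, Group, MapKind
from .heatmap import (
    DEFAULT_RADIUS_PX,
    KernelKind,
    average_maps,
    box_smooth,
    fixations_to_map,
    normalize_map,
)

logger = logging.getLogger(__name__)

DEFAULT_SMOOTH_PX = 11


@dataclass
class GroupAverage:
    """Normalized average gaze map of one group on one stimulus."""

    group: Group
    stimulus_id: str
    map: AttentionMap
    n_participants: int

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("GroupAverage needs at least one contributing participant")


@dataclass
class CommonAttention:
    """A group's generic attention pattern, averaged over all stimuli."""

    group: Group
    map: AttentionMap
    n_stimuli: int


def common_attention(per_stimulus: Sequence[GroupAverage]) -> CommonAttention:
    """Average a group's per-stimulus maps into its common attention pattern."""
    per_stimulus = list(per_stimulus)
    if not per_stimulus:
        raise ValueError("need at least one per-stimulus group average")
    groups = {g.group for g in per_stimulus}
    if len(groups) != 1:
        raise ValueError(f"mixed groups in common_attention input: {sorted(g.value for g in groups)}")
    mean = average_maps([g.map for g in per_stimulus], normalize=True)
    return CommonAttention(
        group=per_stimulus[0].group, map=normalize_map(mean), n_stimuli=len(per_stimulus)
    )


def subtract_common(avg: GroupAverage, common: CommonAttention) -> AttentionMap:
    """Residual attention: per-stimulus average minus the group's common map.

    Negative residuals (less-than-typical attention) are clipped to zero;
    the result is deliberately *not* renormalized, since the absolute amount
    of surplus attention is meaningful. Group labels must match — clinician
    maps are corrected with the clinician common pattern only.
    """
    if avg.group != common.group:
        raise ValueError(
            f"group mismatch: map is {avg.group.value}, common pattern is {common.group.value}"
        )
    if avg.map.shape != common.map.shape:
        raise ValueError("dimension mismatch between map and common pattern")
    residual = np.clip(avg.map.values - common.map.values, 0.0, None)
    return AttentionMap(residual, kind=MapKind.DIFFERENCE)


def group_averages(
    sequences: Sequence[FixationSequence],
    group: Group | str,
    width_px: int,
    height_px: int,
    radius_px: int = DEFAULT_RADIUS_PX,
    kernel: KernelKind = "linear",
) -> dict[str, GroupAverage]:
    """Per-stimulus normalized group-average maps from raw fixation sequences.

    Sequences not belonging to ``group`` are ignored; stimuli with zero
    contributing participants are simply absent from the result. Sequences
    with no fixations contribute nothing (their map has no mass).
    """
    group = Group(group)
    by_stimulus: dict[str, list[AttentionMap]] = {}
    for seq in sequences:
        if seq.group != group:
            continue
        m = fixations_to_map(seq, width_px, height_px, radius_px=radius_px, kernel=kernel)
        if m.total_mass() <= 0:
            logger.warning(
                "participant %s has no fixation mass on stimulus %s; skipped",
                seq.participant_id, seq.stimulus_id,
            )
            continue
        by_stimulus.setdefault(seq.stimulus_id, []).append(m)
    return {
        sid: GroupAverage(
            group=group,
            stimulus_id=sid,
            map=average_maps(maps, normalize=True),
            n_participants=len(maps),
        )
        for sid, maps in sorted(by_stimulus.items())
    }


def preprocess_group(
    sequences: Sequence[FixationSequence],
    group: Group | str,
    width_px: int,
    height_px: int,
    radius_px: int = DEFAULT_RADIUS_PX,
    kernel: KernelKind = "linear",
    smooth_px: int = DEFAULT_SMOOTH_PX,
    common: CommonAttention | None = None,
    per_participant: bool = False,
) -> dict[str, AttentionMap]:
    """Full preprocessing pipeline for one group.

    Per stimulus: render each participant's fixations → normalize → average
    across participants → subtract the group's common attention pattern →
    box-smooth. Returns ``stimulus_id -> residual AttentionMap``. The common
    pattern defaults to the one estimated from these very sequences; pass
    ``common`` to correct a subgroup with its parent group's pattern.

    With ``per_participant=True`` the common pattern is subtracted from each
    participant's normalized map *before* averaging (clipping negatives per
    participant) instead of from the group average. The two orders differ
    because clipping is nonlinear; the average-level default discards less
    signal.

    Deterministic given inputs, and invariant to participant order.
    """
    group = Group(group)
    averages = group_averages(
        sequences, group, width_px, height_px, radius_px=radius_px, kernel=kernel
    )
    if not averages:
        return {}
    if common is None:
        common = common_attention(list(averages.values()))
    if per_participant:
        residuals: dict[str, list[np.ndarray]] = {}
        for seq in sequences:
            if seq.group != group:
                continue
            m = fixations_to_map(seq, width_px, height_px, radius_px=radius_px, kernel=kernel)
            if m.total_mass() <= 0:
                continue
            resid = np.clip(normalize_map(m).values - common.map.values, 0.0, None)
            residuals.setdefault(seq.stimulus_id, []).append(resid)
        return {
            sid: box_smooth(
                AttentionMap(np.mean(stack, axis=0), kind=MapKind.DIFFERENCE), smooth_px
            )
            for sid, stack in sorted(residuals.items())
        }
    out: dict[str, AttentionMap] = {}
    for sid, avg in averages.items():
        residual = subtract_common(avg, common)
        out[sid] = box_smooth(residual, smooth_px)
    return out
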