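"""Occlusion-sensitivity saliency maps for pluggable image classifiers.

The occlusion method slides a square occluder over the image on a stride
grid, re-runs the classifier, and records how much the probability of the
target label drops. A pixel's saliency is the mean drop over all occluder
positions covering it (each interior pixel is covered by exactly
(box/stride)² boxes at the default 20-px box / 10-px stride). Negative
drops — occlusion *helping* the target class — are clipped to zero.

Any classifier can be plugged in through :class:`ClassifierAdapter`; it only
has to map an H×W×C image in [0, 1] to a probability vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .gaze_io import AttentionMap, MapKind
from .compare import ThresholdKind, binarize, iou

DEFAULT_INPUT_SIZE = 448


class ClassifierContractError(ValueError):
    """The plugged-in classifier violated the probability contract."""


@dataclass
class ClassifierAdapter:
    """Minimal contract a classifier must satisfy to yield saliency maps.

    ``predict`` maps an ``(input_size, input_size, channels)`` float image
    with values in [0, 1] to a probability vector over ``labels``
    (nonnegative, summing to 1 within 1e-6).
    """

    predict: Callable[[np.ndarray], np.ndarray]
    labels: list[str]
    input_size: int = DEFAULT_INPUT_SIZE

    def predict_checked(self, image: np.ndarray) -> np.ndarray:
        p = np.asarray(self.predict(image), dtype=np.float64)
        if p.shape != (len(self.labels),):
            raise ClassifierContractError(
                f"expected {len(self.labels)} probabilities, got shape {p.shape}"
            )
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ClassifierContractError(
                f"probabilities must be nonnegative and sum to 1 (sum = {p.sum():.8f})"
            )
        return p


@dataclass(frozen=True)
class OcclusionConfig:
    """Occluder geometry and fill policy."""

    box_px: int = 20
    stride_px: int = 10
    #: what replaces the occluded box: per-channel image mean (least
    #: distribution shift), mid-gray 0.5, or zero
    fill: Literal["mean", "gray", "zero"] = "mean"
    #: attribute each box's drop to its whole footprint (default) or only
    #: to its center stride-cell
    attribution: Literal["footprint", "center"] = "footprint"

    def __post_init__(self) -> None:
        if not 1 <= self.stride_px <= self.box_px:
            raise ValueError("require 1 <= stride_px <= box_px")


def occlusion_map(
    clf: ClassifierAdapter,
    image: np.ndarray,
    label_index: int,
    cfg: OcclusionConfig = OcclusionConfig(),
) -> AttentionMap:
    """Per-pixel saliency of ``label_index`` by systematic occlusion.

    For every box position on the stride grid, the drop
    ``p0 − p(occluded)`` is accumulated over the covered pixels; each
    pixel's saliency is the mean over the boxes covering it, clipped at 0.
    With ``stride_px == box_px`` (no overlap) every pixel has exactly one
    covering box, so the map equals the naive one-box-at-a-time measurement.
    A classifier that ignores its input yields an identically zero map.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    h, w = image.shape[:2]
    if h != clf.input_size or w != clf.input_size:
        raise ValueError(f"image is {h}×{w}, classifier expects {clf.input_size}²")
    if not 0 <= label_index < len(clf.labels):
        raise ValueError(f"label_index {label_index} out of range")
    if cfg.box_px > clf.input_size:
        raise ValueError("occluder larger than the image")

    if cfg.fill == "mean":
        fill = image.mean(axis=(0, 1))
    elif cfg.fill == "gray":
        fill = np.full(image.shape[2], 0.5)
    else:
        fill = np.zeros(image.shape[2])

    p0 = clf.predict_checked(image)[label_index]
    drop_sum = np.zeros((h, w), dtype=np.float64)
    cover = np.zeros((h, w), dtype=np.float64)
    b, s = cfg.box_px, cfg.stride_px
    for y0 in range(0, h - b + 1, s):
        for x0 in range(0, w - b + 1, s):
            occluded = image.copy()
            occluded[y0 : y0 + b, x0 : x0 + b, :] = fill
            drop = p0 - clf.predict_checked(occluded)[label_index]
            if cfg.attribution == "footprint":
                drop_sum[y0 : y0 + b, x0 : x0 + b] += drop
                cover[y0 : y0 + b, x0 : x0 + b] += 1.0
            else:
                cy, cx = y0 + (b - s) // 2, x0 + (b - s) // 2
                drop_sum[cy : cy + s, cx : cx + s] += drop
                cover[cy : cy + s, cx : cx + s] += 1.0
    with np.errstate(invalid="ignore"):
        sal = np.where(cover > 0, drop_sum / np.maximum(cover, 1.0), 0.0)
    np.clip(sal, 0.0, None, out=sal)
    return AttentionMap(sal, kind=MapKind.SALIENCY)


def coverage_count_map(input_size: int, cfg: OcclusionConfig = OcclusionConfig()) -> np.ndarray:
    """How many occluder positions cover each pixel (footprint attribution)."""
    cover = np.zeros((input_size, input_size), dtype=np.int64)
    b, s = cfg.box_px, cfg.stride_px
    for y0 in range(0, input_size - b + 1, s):
        for x0 in range(0, input_size - b + 1, s):
            cover[y0 : y0 + b, x0 : x0 + b] += 1
    return cover


def ensemble_average(maps: Sequence[AttentionMap]) -> AttentionMap:
    """Cell-wise mean of saliency maps from an ensemble (e.g. CV folds)."""
    maps = list(maps)
    if not maps:
        raise ValueError("ensemble_average requires at least one map")
    kinds = {m.kind for m in maps}
    if len(kinds) != 1:
        raise ValueError(f"mixed map kinds in ensemble: {sorted(k.value for k in kinds)}")
    shape = maps[0].shape
    for i, m in enumerate(maps):
        if m.shape != shape:
            raise ValueError(f"map {i} has shape {m.shape}, expected {shape}")
    return AttentionMap(np.mean([m.values for m in maps], axis=0), kind=maps[0].kind)


def resample_nearest(amap: AttentionMap, height_px: int, width_px: int) -> AttentionMap:
    """Nearest-neighbor resampling (preserves mask topology before IoU)."""
    h, w = amap.shape
    rows = np.minimum((np.arange(height_px) * h / height_px).astype(int), h - 1)
    cols = np.minimum((np.arange(width_px) * w / width_px).astype(int), w - 1)
    return AttentionMap(amap.values[np.ix_(rows, cols)], kind=amap.kind)


def saliency_vs_attention(
    sal: AttentionMap,
    att: AttentionMap,
    q_low: float = 0.25,
    q_high: float = 0.75,
) -> dict[ThresholdKind, float]:
    """IoU between a saliency map and a gaze attention map, per threshold.

    Both maps are binarized at the *same* quantile threshold (low, then
    high) before comparison; the saliency map is nearest-neighbor resampled
    to the attention map's dimensions first if needed.
    """
    if sal.shape != att.shape:
        sal = resample_nearest(sal, *att.shape)
    out: dict[ThresholdKind, float] = {}
    for kind in (ThresholdKind.LOW, ThresholdKind.HIGH):
        bs = binarize(sal, kind, q_low, q_high)
        ba = binarize(att, kind, q_low, q_high)
        # cross-source comparison: align kinds by construction
        out[kind] = iou(bs, ba)
    return out
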