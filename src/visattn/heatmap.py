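"""Continuous attention maps from fixation sequences.

Each fixation deposits its duration as mass under a radially decreasing
kernel of fixed pixel support (default radius 25 px, the export setting the
downstream comparisons assume). Kernels are normalized to unit sum, so a
map's total mass equals the summed fixation duration in milliseconds (up to
boundary clipping when a fixation sits near the image edge).
"""

from __future__ import annotations

import functools
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import ndimage

from .gaze_io import AttentionMap, FixationSequence, MapKind

DEFAULT_RADIUS_PX = 25

KernelKind = Literal["linear", "gaussian", "flat"]


class NormalizationError(ValueError):
    """Raised when a map with no mass is asked to become a probability map."""


@functools.lru_cache(maxsize=16)
def _edge_counts(shape: tuple[int, int], kernel_px: int) -> np.ndarray:
    """Fraction of the box window that is in-bounds, per cell (cached)."""
    ones = np.ones(shape)
    return ndimage.uniform_filter(ones, size=kernel_px, mode="constant", cval=0.0)


@functools.lru_cache(maxsize=32)
def _kernel(radius_px: int, kind: KernelKind) -> np.ndarray:
    """Unit-sum radial kernel on a (2r+1)² footprint.

    linear: 1 − r/R clipped at 0 (triangular falloff, the default);
    gaussian: sd = R/2, truncated at R; flat: indicator of the disc.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    ax = np.arange(-radius_px, radius_px + 1, dtype=np.float64)
    r = np.hypot(ax[:, None], ax[None, :])
    if kind == "linear":
        k = np.clip(1.0 - r / radius_px, 0.0, None)
    elif kind == "gaussian":
        sd = radius_px / 2.0
        k = np.exp(-0.5 * (r / sd) ** 2)
        k[r > radius_px] = 0.0
    elif kind == "flat":
        k = (r <= radius_px).astype(np.float64)
    else:
        raise ValueError(f"unknown kernel kind {kind!r}")
    return k / k.sum()


def fixations_to_map(
    seq: FixationSequence,
    width_px: int,
    height_px: int,
    radius_px: int = DEFAULT_RADIUS_PX,
    kernel: KernelKind = "linear",
) -> AttentionMap:
    """Render one participant-trial's fixations as a continuous heat map.

    Every fixation stamps ``duration_ms × kernel`` centered at its (rounded)
    pixel location; contributions add, so the operation is linear in duration
    and additive over fixations. An empty sequence yields an all-zero map.
    Fixation centers outside the image are clipped to the boundary.
    """
    if width_px < 1 or height_px < 1:
        raise ValueError("map dimensions must be positive")
    k = _kernel(radius_px, kernel)
    out = np.zeros((height_px, width_px), dtype=np.float64)
    r = radius_px
    for f in seq.fixations:
        cx = int(round(min(max(f.x_px, 0), width_px - 1)))
        cy = int(round(min(max(f.y_px, 0), height_px - 1)))
        y0, y1 = cy - r, cy + r + 1
        x0, x1 = cx - r, cx + r + 1
        ky0, kx0 = max(0, -y0), max(0, -x0)
        y0, x0 = max(0, y0), max(0, x0)
        y1, x1 = min(height_px, y1), min(width_px, x1)
        out[y0:y1, x0:x1] += f.duration_ms * k[ky0 : ky0 + (y1 - y0), kx0 : kx0 + (x1 - x0)]
    return AttentionMap(out, kind=MapKind.GAZE)


def box_smooth(amap: AttentionMap, kernel_px: int) -> AttentionMap:
    """Box-filter smoothing with truncated-edge handling.

    Each output cell is the arithmetic mean of the ``kernel_px × kernel_px``
    neighborhood, restricted to in-bounds cells near the borders (so a
    constant map stays exactly constant). ``kernel_px`` must be odd;
    ``kernel_px = 1`` is the identity.
    """
    if kernel_px < 1 or kernel_px % 2 == 0:
        raise ValueError(f"kernel_px must be odd and >= 1, got {kernel_px}")
    if kernel_px == 1:
        return AttentionMap(amap.values.copy(), kind=amap.kind)
    # sum over window / count of in-bounds cells = truncated mean
    summed = ndimage.uniform_filter(amap.values, size=kernel_px, mode="constant", cval=0.0)
    out = summed / _edge_counts(amap.values.shape, kernel_px)
    np.clip(out, 0.0, None, out=out)  # guard tiny negative float noise
    return AttentionMap(out, kind=amap.kind)


def normalize_map(amap: AttentionMap) -> AttentionMap:
    """Scale a map to unit total mass (probability-mass convention)."""
    total = amap.values.sum()
    if total <= 0:
        raise NormalizationError("cannot normalize an all-zero attention map")
    return AttentionMap(amap.values / total, kind=amap.kind)


def average_maps(maps: Sequence[AttentionMap], normalize: bool = True) -> AttentionMap:
    """Cell-wise mean of maps, after per-map unit-mass normalization.

    Normalizing first keeps participants with long total fixation time from
    dominating a group average. Pass ``normalize=False`` for a plain mean.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("average_maps requires at least one map")
    shape = maps[0].shape
    for i, m in enumerate(maps):
        if m.shape != shape:
            raise ValueError(f"map {i} has shape {m.shape}, expected {shape}")
    stack = np.stack([normalize_map(m).values if normalize else m.values for m in maps])
    return AttentionMap(stack.mean(axis=0), kind=maps[0].kind)
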