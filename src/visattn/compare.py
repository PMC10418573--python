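"""Thresholded mask comparison of attention maps and pooling across stimuli.

The comparison statistic is intersection-over-union (IoU) between binarized
attention maps. Two quantile thresholds are used: a *low* one that only
strips spurious weak signal, and a *high* one that keeps only the most
attended regions. Per-stimulus IoU uncertainty comes from bootstrapping over
participants; per-stimulus effects are then pooled across stimuli with a
DerSimonian–Laird random-effects meta-analysis (the "RE Model" row of a
forest plot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats as sps

from .gaze_io import AttentionMap, MapKind
from .heatmap import average_maps

DEFAULT_Q_LOW = 0.25
DEFAULT_Q_HIGH = 0.75

#: floor applied to zero standard errors so degenerate (single-participant)
#: groups do not get infinite meta-analytic weight
SE_FLOOR = 1e-6


class ThresholdKind(str, Enum):
    LOW = "low"
    HIGH = "high"


@dataclass
class BinaryMap:
    """0/1 mask from quantile-thresholding an attention map."""

    mask: np.ndarray
    threshold_kind: ThresholdKind
    source_kind: MapKind

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.threshold_kind = ThresholdKind(self.threshold_kind)
        self.source_kind = MapKind(self.source_kind)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class EffectEstimate:
    """Per-stimulus IoU with its bootstrap standard error."""

    stimulus_id: str
    effect: float
    se: float
    n_boot: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError(f"IoU effect must lie in [0, 1], got {self.effect}")
        if not np.isfinite(self.se) or self.se < 0:
            raise ValueError(f"standard error must be finite and >= 0, got {self.se}")


@dataclass
class MetaResult:
    """Random-effects pooled summary over stimuli."""

    pooled_effect: float
    ci_low: float
    ci_high: float
    tau2: float
    q_stat: float
    k: int

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if not self.ci_low <= self.pooled_effect <= self.ci_high:
            raise ValueError("pooled effect must lie inside its CI")


def binarize(
    amap: AttentionMap,
    kind: ThresholdKind | str,
    q_low: float = DEFAULT_Q_LOW,
    q_high: float = DEFAULT_Q_HIGH,
) -> BinaryMap:
    """Quantile-threshold an attention map into a 0/1 mask.

    The threshold is the ``q``-quantile of the map's *nonzero* values
    (``q = q_low`` for the low threshold, ``q_high`` for the high one);
    cells strictly above it become 1. Quantiles are taken over nonzero cells
    only because most of a face stimulus is zero-attention background, which
    would otherwise drive every threshold to zero. An all-zero map yields an
    all-zero mask. The high mask is always a subset of the low mask.
    """
    kind = ThresholdKind(kind)
    for name, q in (("q_low", q_low), ("q_high", q_high)):
        if not 0.0 < q < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {q}")
    vals = amap.values
    if np.any(vals < 0):
        raise ValueError("binarize expects a nonnegative map; clip difference maps first")
    nz = vals[vals > 0]
    if nz.size == 0:
        mask = np.zeros(vals.shape, dtype=bool)
    else:
        t = float(np.quantile(nz, q_low if kind is ThresholdKind.LOW else q_high))
        mask = vals > t
    return BinaryMap(mask, threshold_kind=kind, source_kind=amap.kind)


def iou(a: BinaryMap, b: BinaryMap) -> float:
    """Intersection-over-union of two masks: |a ∧ b| / |a ∨ b| ∈ [0, 1].

    Masks must share dimensions and threshold kind (compare like with like).
    If both masks are empty the union is empty; IoU is defined as 0 with a
    warning so downstream pooling stays finite.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask dimension mismatch: {a.shape} vs {b.shape}")
    if a.threshold_kind != b.threshold_kind:
        raise ValueError(
            f"threshold kind mismatch: {a.threshold_kind.value} vs {b.threshold_kind.value}"
        )
    union = int(np.logical_or(a.mask, b.mask).sum())
    if union == 0:
        warnings.warn("IoU of two empty masks; defined as 0", stacklevel=2)
        return 0.0
    inter = int(np.logical_and(a.mask, b.mask).sum())
    return inter / union


MapTransform = Callable[[AttentionMap], AttentionMap]


def bootstrap_iou(
    group_a: Sequence[AttentionMap],
    group_b: Sequence[AttentionMap],
    kind: ThresholdKind | str,
    q_low: float = DEFAULT_Q_LOW,
    q_high: float = DEFAULT_Q_HIGH,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    transform_a: MapTransform | None = None,
    transform_b: MapTransform | None = None,
    stimulus_id: str = "",
) -> EffectEstimate:
    """IoU between two groups' average maps, with bootstrap standard error.

    ``group_a`` and ``group_b`` hold one attention map per participant. The
    point estimate averages each full group, applies the optional transform
    (e.g. common-attention subtraction + smoothing), binarizes at ``kind``,
    and takes the IoU. Each bootstrap replicate resamples participants *with
    replacement within each group independently* — the participant is the
    exchangeable unit — and recomputes the same statistic; ``se`` is the
    standard deviation of the replicates. Reproducible given ``seed``.
    """
    kind = ThresholdKind(kind)
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one participant map")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ident: MapTransform = lambda m: m
    ta = transform_a or ident
    tb = transform_b or ident

    # pre-normalize once; replicate averages are plain means of these stacks
    stack_a = np.stack([m.values / m.values.sum() for m in group_a]).astype(np.float32)
    stack_b = np.stack([m.values / m.values.sum() for m in group_b]).astype(np.float32)
    kind_a, kind_b = group_a[0].kind, group_b[0].kind

    def statistic(vals_a: np.ndarray, vals_b: np.ndarray) -> float:
        ma = ta(AttentionMap(vals_a.astype(np.float64), kind=kind_a))
        mb = tb(AttentionMap(vals_b.astype(np.float64), kind=kind_b))
        return iou(
            binarize(ma, kind, q_low, q_high),
            binarize(mb, kind, q_low, q_high),
        )

    # a replicate's group average is a weighted mean of the per-participant
    # maps with multinomial resample counts as weights
    flat_a = stack_a.reshape(len(group_a), -1)
    flat_b = stack_b.reshape(len(group_b), -1)
    shape = group_a[0].shape

    def resampled_mean(flat: np.ndarray, idx: np.ndarray) -> np.ndarray:
        w = np.bincount(idx, minlength=flat.shape[0]).astype(np.float32) / len(idx)
        return (w @ flat).reshape(shape)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty-mask warnings inside replicates
        effect = statistic(flat_a.mean(axis=0).reshape(shape), flat_b.mean(axis=0).reshape(shape))
        na, nb = len(group_a), len(group_b)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            ia = rng.integers(0, na, size=na)
            ib = rng.integers(0, nb, size=nb)
            reps[i] = statistic(resampled_mean(flat_a, ia), resampled_mean(flat_b, ib))
    se = float(reps.std(ddof=1))
    return EffectEstimate(stimulus_id=stimulus_id, effect=float(effect), se=se, n_boot=n_boot)


def re_meta_analysis(effects: Sequence[EffectEstimate]) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of per-stimulus effects.

    With per-stimulus effects y_i and standard errors se_i, fixed-effect
    weights are w_i = 1/se_i²; Cochran's Q = Σ w_i (y_i − ȳ_w)²; the
    between-stimulus variance is

        τ² = max(0, (Q − (k − 1)) / (Σw_i − Σw_i² / Σw_i))

    and random-effects weights w*_i = 1/(se_i² + τ²) give the pooled effect
    Σ w*_i y_i / Σ w*_i with 95% CI pooled ± 1.96 (Σ w*_i)^(−1/2).
    When τ² = 0 this reduces exactly to fixed-effect inverse-variance
    pooling. Zero standard errors are floored at ``SE_FLOOR`` with a warning.
    """
    effects = list(effects)
    k = len(effects)
    if k < 2:
        raise ValueError("random-effects pooling needs at least 2 stimuli")
    y = np.array([e.effect for e in effects], dtype=np.float64)
    se = np.array([e.se for e in effects], dtype=np.float64)
    if np.any(se <= 0):
        warnings.warn(
            f"{int((se <= 0).sum())} zero standard error(s) floored at {SE_FLOOR}",
            stacklevel=2,
        )
        se = np.maximum(se, SE_FLOOR)

    w = 1.0 / se**2
    y_fixed = float((w * y).sum() / w.sum())
    q = float((w * (y - y_fixed) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * y).sum() / w_star.sum())
    se_pooled = float(w_star.sum() ** -0.5)
    return MetaResult(
        pooled_effect=pooled,
        ci_low=pooled - 1.96 * se_pooled,
        ci_high=pooled + 1.96 * se_pooled,
        tau2=float(tau2),
        q_stat=q,
        k=k,
    )
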