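"""Synthetic eye-tracking study generator.

Emulates the structure of a two-group face-inspection experiment so the
whole pipeline can be exercised without any deposited data: 16 stimuli
viewed for 7 s each by 22 clinicians and 22 non-clinicians, fixation
streams with a planted attention structure, affected/unaffected responses
at configurable target accuracies, and a toy classifier whose occlusion
saliency is analytically known.

Gaze is modeled as a Gaussian mixture: three *common* components at fixed
eye/nose/mouth coordinates shared by every stimulus (generic face-viewing
behavior), plus one *stimulus-specific* component per stimulus at a random
location — the planted "dysmorphic feature" — whose mixture weight is
higher for clinicians than non-clinicians. This is the simplest generative
model reproducing the qualitative structure the pipeline is designed to
detect; it is not a claim about gaze physiology.

All generators are pure functions of (config, seed): the same config yields
byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .gaze_io import AOISet, Fixation, FixationSequence, Group
from .saliency import ClassifierAdapter
from .stats import ResponseRecord

# fixed common-attention geometry, as fractions of the image side
_COMMON_LAYOUT: tuple[tuple[str, float, float, float, float], ...] = (
    # name, fx, fy, sd_frac, weight
    ("eyes", 0.50, 0.35, 0.090, 0.45),
    ("nose", 0.50, 0.55, 0.060, 0.30),
    ("mouth", 0.50, 0.72, 0.060, 0.25),
)

_SPECIFIC_SD_FRAC = 0.05
_PLACEMENT_MARGIN = 0.16  # keep planted features away from borders
_MIN_SEP_FRAC = 0.18  # and away from the common component centers


@dataclass(frozen=True)
class MixtureComponent:
    center_xy: tuple[float, float]  # pixels
    sd_px: float
    weight: float


@dataclass(frozen=True)
class AttentionProfile:
    """A weighted Gaussian mixture describing where a viewer's gaze lands."""

    components: tuple[MixtureComponent, ...]
    label: Literal["common", "group_specific", "stimulus_specific"]

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.components)
        if not self.components or any(c.weight <= 0 for c in self.components):
            raise ValueError("profile weights must be positive")
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"profile weights must sum to 1, got {w}")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulated experiment: 22 clinicians and 22
    non-clinicians, 16 images (10 affected / 6 unaffected) at 448 px,
    7 s viewing per image, and target judgment accuracies of 85.6% /
    76.9%. Fixation durations are Gamma(shape 2) with 300 ms mean —
    a typical fixation-duration scale.
    """

    n_clinicians: int = 22
    n_non_clinicians: int = 22
    n_stimuli: int = 16
    n_affected: int = 10
    image_px: int = 448
    viewing_ms: float = 7000.0
    fixations_per_trial: float = 18.0
    duration_shape: float = 2.0
    duration_mean_ms: float = 300.0
    #: mixture weight of the planted stimulus-specific feature, per group;
    #: clinicians attend the dysmorphic feature more than non-clinicians
    specific_weight: Mapping[str, float] = field(
        default_factory=lambda: {"clinician": 0.35, "non_clinician": 0.12}
    )
    #: when True, each group gets its *own* planted feature location per
    #: stimulus (disjoint group-specific attention); when False both groups
    #: share one feature location
    disjoint_specific: bool = False
    group_accuracy: Mapping[str, float] = field(
        default_factory=lambda: {"clinician": 0.856, "non_clinician": 0.769}
    )
    #: fraction of correct clinician responses on affected stimuli that also
    #: name the condition
    named_condition_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_affected > self.n_stimuli:
            raise ValueError("n_affected cannot exceed n_stimuli")
        if min(self.n_clinicians, self.n_non_clinicians, self.n_stimuli, self.image_px) < 1:
            raise ValueError("counts and image size must be positive")
        for g, a in self.group_accuracy.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"accuracy for {g} must lie in [0, 1]")


@dataclass(frozen=True)
class Stimulus:
    """One synthetic test image with its planted attention structure."""

    stimulus_id: str
    truth: str  # affected | unaffected
    condition: str | None
    image: np.ndarray  # (image_px, image_px) floats in [0, 1]
    common_profile: AttentionProfile
    specific_profiles: Mapping[Group, AttentionProfile]
    aoi_set: AOISet
    target_region: tuple[int, int, int, int]  # x0, y0, x1, y1 (exclusive)


def _rng(seed: int, *streams: str | int) -> np.random.Generator:
    """Independent, reproducible substream keyed by seed plus string/int tags."""
    tags = [zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in streams]
    return np.random.default_rng([int(seed) % 2**31, *tags])


def common_profile(image_px: int) -> AttentionProfile:
    """The fixed eyes/nose/mouth mixture every stimulus shares."""
    comps = tuple(
        MixtureComponent((fx * image_px, fy * image_px), sd * image_px, w)
        for _, fx, fy, sd, w in _COMMON_LAYOUT
    )
    return AttentionProfile(comps, label="common")


def _place_specific(rng: np.random.Generator) -> tuple[float, float]:
    """Random feature location (fractions), kept clear of borders and of the
    common component centers so the planted signal is identifiable."""
    centers = [(fx, fy) for _, fx, fy, _, _ in _COMMON_LAYOUT]
    for _ in range(1000):
        x = rng.uniform(_PLACEMENT_MARGIN, 1 - _PLACEMENT_MARGIN)
        y = rng.uniform(_PLACEMENT_MARGIN, 1 - _PLACEMENT_MARGIN)
        if all(np.hypot(x - cx, y - cy) >= _MIN_SEP_FRAC for cx, cy in centers):
            return x, y
    raise RuntimeError("could not place a stimulus-specific component")


def _bump(px: int, cx: float, cy: float, sd: float) -> np.ndarray:
    yy, xx = np.mgrid[0:px, 0:px].astype(np.float64)
    return np.exp(-0.5 * ((xx - cx) ** 2 + (yy - cy) ** 2) / sd**2)


def gen_stimuli(cfg: CohortConfig) -> list[Stimulus]:
    """Generate the stimulus set: images, planted profiles, AOIs, truths.

    Each stimulus image is a smooth random field with brightened regions at
    the common and planted-feature locations (no faces are synthesized).
    The planted feature gets an octagonal AOI and a square target region
    for the toy classifier. The first ``n_affected`` stimuli are affected.
    """
    px = cfg.image_px
    common = common_profile(px)
    stimuli: list[Stimulus] = []
    for i in range(cfg.n_stimuli):
        rng = _rng(cfg.seed, "stimuli", i)
        affected = i < cfg.n_affected
        sid = f"stim-{i:02d}"

        sd_px = _SPECIFIC_SD_FRAC * px
        fx, fy = _place_specific(rng)
        spec_clin = AttentionProfile(
            (MixtureComponent((fx * px, fy * px), sd_px, 1.0),), label="stimulus_specific"
        )
        if cfg.disjoint_specific:
            fx2, fy2 = _place_specific(rng)
            # resample until the two group features are well separated
            for _ in range(1000):
                if np.hypot(fx2 - fx, fy2 - fy) >= 2.5 * _SPECIFIC_SD_FRAC + _MIN_SEP_FRAC / 2:
                    break
                fx2, fy2 = _place_specific(rng)
            spec_non = AttentionProfile(
                (MixtureComponent((fx2 * px, fy2 * px), sd_px, 1.0),),
                label="stimulus_specific",
            )
        else:
            spec_non = spec_clin
        specific = {Group.CLINICIAN: spec_clin, Group.NON_CLINICIAN: spec_non}

        # smooth random background field plus brightened component regions
        base = ndimage.gaussian_filter(rng.uniform(0.0, 1.0, size=(px, px)), sigma=px / 16)
        base = 0.15 + 0.25 * (base - base.min()) / max(np.ptp(base), 1e-12)
        img = base.copy()
        for comp in common.components:
            img += 0.25 * _bump(px, *comp.center_xy, comp.sd_px)
        img += 0.6 * _bump(px, fx * px, fy * px, sd_px)
        img = np.clip(img, 0.0, 1.0)

        # octagonal AOI around the planted feature
        r = 2.5 * sd_px
        ang = np.linspace(0, 2 * np.pi, 9)[:-1]
        verts = [
            (fx * px + r * np.cos(a), fy * px + r * np.sin(a)) for a in ang
        ]
        aoi = AOISet(stimulus_id=sid, aois=[("planted-feature", Polygon(verts))])

        half = int(round(1.2 * sd_px))
        cx, cy = int(round(fx * px)), int(round(fy * px))
        region = (
            max(0, cx - half), max(0, cy - half),
            min(px, cx + half), min(px, cy + half),
        )
        stimuli.append(
            Stimulus(
                stimulus_id=sid,
                truth="affected" if affected else "unaffected",
                condition=f"cond-{i:02d}" if affected else None,
                image=img,
                common_profile=common,
                specific_profiles=specific,
                aoi_set=aoi,
                target_region=region,
            )
        )
    return stimuli


def trial_mixture(cfg: CohortConfig, stimulus: Stimulus, group: Group) -> AttentionProfile:
    """The full gaze mixture a participant of ``group`` uses on ``stimulus``."""
    w_spec = float(cfg.specific_weight[Group(group).value])
    if not 0.0 <= w_spec < 1.0:
        raise ValueError("specific weight must lie in [0, 1)")
    comps = [
        MixtureComponent(c.center_xy, c.sd_px, c.weight * (1.0 - w_spec))
        for c in stimulus.common_profile.components
    ]
    if w_spec > 0:
        spec = stimulus.specific_profiles[Group(group)]
        comps.extend(
            MixtureComponent(c.center_xy, c.sd_px, c.weight * w_spec) for c in spec.components
        )
    return AttentionProfile(tuple(comps), label="common")


def sample_profile(
    profile: AttentionProfile, n: int, rng: np.random.Generator, image_px: int
) -> np.ndarray:
    """Sample (n, 2) fixation locations (x, y) from a mixture, clipped to bounds."""
    weights = np.array([c.weight for c in profile.components])
    idx = rng.choice(len(profile.components), size=n, p=weights / weights.sum())
    out = np.empty((n, 2))
    for i, c in enumerate(profile.components):
        m = idx == i
        k = int(m.sum())
        if k:
            out[m] = rng.normal(loc=c.center_xy, scale=c.sd_px, size=(k, 2))
    return np.clip(out, 0.0, image_px - 1.0)


def gen_fixations(
    cfg: CohortConfig,
    stimuli: Sequence[Stimulus],
    participant_id: str,
    group: Group | str,
) -> list[FixationSequence]:
    """One participant's fixation sequences over all stimuli.

    Per trial the fixation count is Poisson(``fixations_per_trial``),
    locations come from the trial mixture, durations are Gamma with the
    configured shape and mean, and inter-fixation gaps are uniform
    30–90 ms saccade intervals. If the sampled trial overruns the viewing
    window, durations and gaps are rescaled so onset + duration never
    exceeds it.
    """
    group = Group(group)
    sequences: list[FixationSequence] = []
    for stim in stimuli:
        rng = _rng(cfg.seed, "fixations", participant_id, stim.stimulus_id)
        n = int(rng.poisson(cfg.fixations_per_trial))
        if n == 0:
            sequences.append(FixationSequence(participant_id, group, stim.stimulus_id, []))
            continue
        mixture = trial_mixture(cfg, stim, group)
        locs = sample_profile(mixture, n, rng, cfg.image_px)
        shape = cfg.duration_shape
        durations = rng.gamma(shape, cfg.duration_mean_ms / shape, size=n)
        durations = np.maximum(durations, 20.0)  # physiological floor
        gaps = rng.uniform(30.0, 90.0, size=n)
        total = durations.sum() + gaps.sum()
        if total > cfg.viewing_ms:
            scale = cfg.viewing_ms / total * (1.0 - 1e-9)
            durations *= scale
            gaps *= scale
        onsets = np.cumsum(gaps) + np.concatenate([[0.0], np.cumsum(durations[:-1])])
        fixes = [
            Fixation(float(x), float(y), float(o), float(d))
            for (x, y), o, d in zip(locs, onsets, durations)
        ]
        sequences.append(FixationSequence(participant_id, group, stim.stimulus_id, fixes))
    return sequences


def participant_ids(cfg: CohortConfig) -> dict[Group, list[str]]:
    return {
        Group.CLINICIAN: [f"clin-{i:02d}" for i in range(cfg.n_clinicians)],
        Group.NON_CLINICIAN: [f"non-{i:02d}" for i in range(cfg.n_non_clinicians)],
    }


def gen_responses(cfg: CohortConfig, stimuli: Sequence[Stimulus]) -> list[ResponseRecord]:
    """Affected/unaffected judgments at the configured target accuracies.

    Each (participant, stimulus) judgment is an independent Bernoulli draw:
    correct with probability ``group_accuracy[group]``, otherwise flipped.
    A configurable fraction of correct clinician responses on affected
    stimuli also carries the named condition.
    """
    records: list[ResponseRecord] = []
    for group, pids in participant_ids(cfg).items():
        acc = float(cfg.group_accuracy[group.value])
        for pid in pids:
            for stim in stimuli:
                rng = _rng(cfg.seed, "responses", pid, stim.stimulus_id)
                correct = bool(rng.random() < acc)
                judgment = (
                    stim.truth
                    if correct
                    else ("unaffected" if stim.truth == "affected" else "affected")
                )
                named = None
                if (
                    correct
                    and group is Group.CLINICIAN
                    and stim.truth == "affected"
                    and rng.random() < cfg.named_condition_fraction
                ):
                    named = stim.condition
                records.append(
                    ResponseRecord(
                        participant_id=pid,
                        group=group,
                        stimulus_id=stim.stimulus_id,
                        truth=stim.truth,
                        judgment=judgment,
                        named_condition=named,
                    )
                )
    return records


def gen_cohort(
    cfg: CohortConfig,
) -> tuple[list[Stimulus], list[FixationSequence], list[ResponseRecord]]:
    """Full synthetic study: stimuli, everyone's fixations, all responses."""
    stimuli = gen_stimuli(cfg)
    sequences: list[FixationSequence] = []
    for group, pids in participant_ids(cfg).items():
        for pid in pids:
            sequences.extend(gen_fixations(cfg, stimuli, pid, group))
    responses = gen_responses(cfg, stimuli)
    return stimuli, sequences, responses


def toy_classifier(
    stimulus: Stimulus,
    target_region: tuple[int, int, int, int] | None = None,
    labels: Sequence[str] | None = None,
    true_label_index: int = 0,
    gain: float = 4.0,
) -> ClassifierAdapter:
    """A classifier whose saliency is analytically known.

    The probability of the true label is a logistic function of the *mean*
    pixel intensity inside ``target_region`` (default: the stimulus's own
    planted-feature box): ``p = sigmoid(gain · mean_intensity)``. The
    remaining mass is spread evenly over the other labels, so the adapter
    satisfies the probability contract and is invariant to relabeling the
    non-target classes. Occluding pixels outside the region cannot change
    the prediction; occlusion saliency therefore concentrates exactly on
    the target region. An image with zero intensity in the region scores
    probability 0.5.
    """
    px = stimulus.image.shape[0]
    region = target_region if target_region is not None else stimulus.target_region
    x0, y0, x1, y1 = region
    if not (0 <= x0 < x1 <= px and 0 <= y0 < y1 <= px):
        raise ValueError(f"target region {region} outside image bounds (0..{px})")
    if labels is None:
        labels = [stimulus.stimulus_id, "other"]
    labels = list(labels)
    if not 0 <= true_label_index < len(labels):
        raise ValueError("true_label_index out of range")
    area = (x1 - x0) * (y1 - y0)

    def predict(image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        if image.ndim == 3:
            image = image.mean(axis=2)
        s = image[y0:y1, x0:x1].sum() / area
        p_true = 1.0 / (1.0 + np.exp(-gain * s))
        p = np.full(len(labels), (1.0 - p_true) / (len(labels) - 1))
        p[true_label_index] = p_true
        return p

    return ClassifierAdapter(predict=predict, labels=labels, input_size=px)
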