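"""End-to-end orchestration: simulate → preprocess → compare → saliency → stats.

The pipeline mirrors the study's analysis plan. Participants are divided,
*per stimulus*, into successful and underperforming subgroups (those who
did / did not judge that stimulus correctly — the same participant can be
successful on one image and underperforming on another). Subgroup average
maps are corrected with their parent group's common attention pattern,
smoothed, binarized at a low and a high quantile threshold, and compared
by IoU with bootstrap standard errors; per-stimulus effects are pooled
across stimuli with a random-effects meta-analysis. Optionally the toy
classifier's occlusion saliency maps are compared against the human maps
at the same thresholds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .compare import (
    EffectEstimate,
    MetaResult,
    ThresholdKind,
    bootstrap_iou,
    re_meta_analysis,
)
from .gaze_io import AttentionMap, FixationSequence, Group, MapKind
from .heatmap import box_smooth, fixations_to_map, normalize_map
from .preprocess import CommonAttention, GroupAverage, common_attention, subtract_common
from .saliency import OcclusionConfig, occlusion_map
from .stats import ResponseRecord, accuracy, aoi_metrics_table, build_contingency, chi_square
from .synthetic import CohortConfig, Stimulus, gen_cohort, toy_classifier

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An analysis stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """One config object driving the whole analysis."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    radius_px: int = 25
    kernel: str = "linear"
    smooth_px: int = 11
    q_low: float = 0.25
    q_high: float = 0.75
    n_boot: int = 200
    include_saliency: bool = True
    occlusion_box_px: int = 20
    occlusion_stride_px: int = 10

    @property
    def seed(self) -> int:
        return self.cohort.seed

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        cohort = CohortConfig(**data.pop("cohort", {}))
        return cls(cohort=cohort, **data)


def subgroup_members(
    responses: Sequence[ResponseRecord],
) -> dict[tuple[str, Group, bool], set[str]]:
    """Per-stimulus subgroup membership.

    Maps ``(stimulus_id, group, correct)`` to the set of participant ids in
    that subgroup. Membership is evaluated independently per stimulus;
    missing judgments belong to neither subgroup.
    """
    out: dict[tuple[str, Group, bool], set[str]] = {}
    for r in responses:
        if r.is_missing:
            continue
        key = (r.stimulus_id, Group(r.group), r.is_correct)
        out.setdefault(key, set()).add(r.participant_id)
    return out


def participant_maps(
    sequences: Sequence[FixationSequence],
    width_px: int,
    height_px: int,
    radius_px: int = 25,
    kernel: str = "linear",
) -> dict[str, dict[tuple[str, Group], AttentionMap]]:
    """Normalized per-participant maps, keyed ``stimulus_id → (pid, group)``.

    Sequences with no fixation mass are skipped (absent data, as when an
    eye-tracking result was discarded).
    """
    out: dict[str, dict[tuple[str, Group], AttentionMap]] = {}
    for seq in sequences:
        m = fixations_to_map(seq, width_px, height_px, radius_px=radius_px, kernel=kernel)
        if m.total_mass() <= 0:
            continue
        out.setdefault(seq.stimulus_id, {})[(seq.participant_id, seq.group)] = normalize_map(m)
    return out


def _group_common(
    maps_by_stim: Mapping[str, Mapping[tuple[str, Group], AttentionMap]], group: Group
) -> CommonAttention:
    averages = []
    for sid, maps in sorted(maps_by_stim.items()):
        group_maps = [m for (pid, g), m in maps.items() if g == group]
        if not group_maps:
            continue
        stack = np.stack([m.values for m in group_maps])
        averages.append(
            GroupAverage(
                group=group,
                stimulus_id=sid,
                map=AttentionMap(stack.mean(axis=0)),
                n_participants=len(group_maps),
            )
        )
    if not averages:
        raise PipelineError(f"no data for group {group.value}")
    return common_attention(averages)


def _residual_transform(common: CommonAttention, smooth_px: int):
    """avg map → subtract the parent group's common pattern → box smooth."""

    def transform(avg: AttentionMap) -> AttentionMap:
        residual = np.clip(avg.values - common.map.values, 0.0, None)
        return box_smooth(AttentionMap(residual, kind=MapKind.DIFFERENCE), smooth_px)

    return transform


@dataclass
class ComparisonResult:
    name: str
    kind: ThresholdKind
    per_stimulus: list[EffectEstimate]
    re_model: MetaResult


def _compare_subgroups(
    name: str,
    maps_by_stim: Mapping[str, Mapping[tuple[str, Group], AttentionMap]],
    members_a: Mapping[str, set[str]],
    members_b: Mapping[str, set[str]],
    group_a: Group,
    group_b: Group,
    commons: Mapping[Group, CommonAttention],
    cfg: RunConfig,
    rng: np.random.Generator,
) -> list[ComparisonResult]:
    ta = _residual_transform(commons[group_a], cfg.smooth_px)
    tb = _residual_transform(commons[group_b], cfg.smooth_px)
    results = []
    for kind in (ThresholdKind.LOW, ThresholdKind.HIGH):
        effects = []
        for sid in sorted(maps_by_stim):
            maps = maps_by_stim[sid]
            a = [m for (pid, g), m in sorted(maps.items()) if g == group_a and pid in members_a.get(sid, ())]
            b = [m for (pid, g), m in sorted(maps.items()) if g == group_b and pid in members_b.get(sid, ())]
            if not a or not b:
                logger.warning("comparison %s: stimulus %s lacks members in one subgroup", name, sid)
                continue
            effects.append(
                bootstrap_iou(
                    a, b, kind,
                    q_low=cfg.q_low, q_high=cfg.q_high,
                    n_boot=cfg.n_boot, seed=rng,
                    transform_a=ta, transform_b=tb,
                    stimulus_id=sid,
                )
            )
        if len(effects) < 2:
            logger.warning("comparison %s (%s): fewer than 2 stimuli; skipped", name, kind.value)
            continue
        results.append(ComparisonResult(name, kind, effects, re_meta_analysis(effects)))
    return results


def run_pipeline(cfg: RunConfig, out_dir: str | None = None) -> dict:
    """Run the full synthetic-study analysis and return the report bundle.

    Deterministic given the config (which carries the seed). The bundle
    holds the accuracy/chi-square analysis, per-stimulus IoU effects and
    RE-model rows for each subgroup comparison, the optional saliency
    comparisons, AOI metrics, and provenance. With ``out_dir`` set, TSV/JSON
    artifacts are also written there.
    """
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": cfg.seed,
            "config_hash": hashlib.sha256(
                json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
        }
    }

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 — re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrap

    stimuli, sequences, responses = stage("simulate")(gen_cohort, cfg.cohort)
    px = cfg.cohort.image_px

    # --- stats stage -------------------------------------------------------
    table = stage("stats")(build_contingency, responses)
    stat, p = chi_square(table)
    report["contingency"] = table.counts.tolist()
    report["accuracy_pct"] = accuracy(table)
    report["chi_square"] = {"statistic": stat, "p": p}

    aoi_df = stage("stats")(
        aoi_metrics_table, sequences, {s.stimulus_id: s.aoi_set for s in stimuli}
    )
    if not aoi_df.empty:
        grp = aoi_df.groupby("group")
        report["aoi_summary"] = {
            g: {
                "mean_duration_of_fixation_ms": float(sub["duration_of_fixation_ms"].mean()),
                "mean_time_to_first_whole_fixation_ms": float(
                    sub["time_to_first_whole_fixation_ms"].dropna().mean()
                ),
                "n_trials": int(len(sub)),
            }
            for g, sub in grp
        }

    # --- preprocess stage --------------------------------------------------
    maps_by_stim = stage("preprocess")(
        participant_maps, sequences, px, px, cfg.radius_px, cfg.kernel
    )
    commons = {
        g: stage("preprocess")(_group_common, maps_by_stim, g)
        for g in (Group.CLINICIAN, Group.NON_CLINICIAN)
    }

    # --- compare stage -----------------------------------------------------
    members = subgroup_members(responses)

    def by_stim(group: Group, correct: bool) -> dict[str, set[str]]:
        return {
            sid: pids
            for (sid, g, c), pids in members.items()
            if g == group and c == correct
        }

    rng = np.random.default_rng(cfg.seed)
    comparison_plan = [
        ("successful_clin_vs_successful_non",
         by_stim(Group.CLINICIAN, True), by_stim(Group.NON_CLINICIAN, True),
         Group.CLINICIAN, Group.NON_CLINICIAN),
        ("successful_vs_underperforming_clin",
         by_stim(Group.CLINICIAN, True), by_stim(Group.CLINICIAN, False),
         Group.CLINICIAN, Group.CLINICIAN),
        ("successful_vs_underperforming_non",
         by_stim(Group.NON_CLINICIAN, True), by_stim(Group.NON_CLINICIAN, False),
         Group.NON_CLINICIAN, Group.NON_CLINICIAN),
        ("underperforming_clin_vs_underperforming_non",
         by_stim(Group.CLINICIAN, False), by_stim(Group.NON_CLINICIAN, False),
         Group.CLINICIAN, Group.NON_CLINICIAN),
    ]
    report["comparisons"] = {}
    for name, ma, mb, ga, gb in comparison_plan:
        results = stage("compare")(
            _compare_subgroups, name, maps_by_stim, ma, mb, ga, gb, commons, cfg, rng
        )
        report["comparisons"][name] = {r.kind.value: _comparison_dict(r) for r in results}

    # --- saliency stage (optional) ----------------------------------------
    if cfg.include_saliency:
        occ = OcclusionConfig(box_px=cfg.occlusion_box_px, stride_px=cfg.occlusion_stride_px)
        sal_results = stage("saliency")(
            _saliency_comparisons, stimuli, maps_by_stim, by_stim(Group.CLINICIAN, True),
            commons, occ, cfg, rng,
        )
        report["comparisons"].update(sal_results)

    if out_dir is not None:
        _write_outputs(report, aoi_df, out_dir)
    return report


def _saliency_comparisons(
    stimuli: Sequence[Stimulus],
    maps_by_stim,
    successful_clin: Mapping[str, set[str]],
    commons,
    occ: OcclusionConfig,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> dict:
    """Toy-classifier occlusion saliency vs. successful clinicians, per threshold.

    Only affected stimuli are compared (saliency targets the condition
    label). The saliency map enters as a fixed single 'participant'; the
    bootstrap therefore reflects human sampling variability only.
    """
    ta = _residual_transform(commons[Group.CLINICIAN], cfg.smooth_px)
    effects: dict[ThresholdKind, list[EffectEstimate]] = {k: [] for k in ThresholdKind}
    for stim in stimuli:
        if stim.truth != "affected":
            continue
        clf = toy_classifier(stim)
        sal = occlusion_map(clf, stim.image, label_index=0, cfg=occ)
        if sal.total_mass() <= 0:
            logger.warning("saliency map for %s is all-zero; skipped", stim.stimulus_id)
            continue
        maps = maps_by_stim.get(stim.stimulus_id, {})
        humans = [
            m for (pid, g), m in sorted(maps.items())
            if g == Group.CLINICIAN and pid in successful_clin.get(stim.stimulus_id, ())
        ]
        if not humans:
            continue
        for kind in ThresholdKind:
            effects[kind].append(
                bootstrap_iou(
                    humans, [sal], kind,
                    q_low=cfg.q_low, q_high=cfg.q_high,
                    n_boot=cfg.n_boot, seed=rng,
                    transform_a=ta, transform_b=None,
                    stimulus_id=stim.stimulus_id,
                )
            )
    out: dict = {"saliency_vs_successful_clin": {}}
    for kind, effs in effects.items():
        if len(effs) >= 2:
            res = ComparisonResult("saliency_vs_successful_clin", kind, effs, re_meta_analysis(effs))
            out["saliency_vs_successful_clin"][kind.value] = _comparison_dict(res)
    return out


def _comparison_dict(r: ComparisonResult) -> dict:
    return {
        "per_stimulus": [
            {"stimulus_id": e.stimulus_id, "effect": e.effect, "se": e.se, "n_boot": e.n_boot}
            for e in r.per_stimulus
        ],
        "re_model": {
            "pooled_effect": r.re_model.pooled_effect,
            "ci_low": r.re_model.ci_low,
            "ci_high": r.re_model.ci_high,
            "tau2": r.re_model.tau2,
            "q_stat": r.re_model.q_stat,
            "k": r.re_model.k,
        },
    }


def _write_outputs(report: dict, aoi_df: pd.DataFrame, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    if not aoi_df.empty:
        aoi_df.to_csv(os.path.join(out_dir, "aoi_metrics.tsv"), sep="\t", index=False)
    for name, kinds in report.get("comparisons", {}).items():
        for kind, data in kinds.items():
            rows = [
                {"stimulus_id": e["stimulus_id"], "effect": e["effect"], "se": e["se"]}
                for e in data["per_stimulus"]
            ]
            re = data["re_model"]
            rows.append(
                {"stimulus_id": "RE_MODEL", "effect": re["pooled_effect"], "se": "",
                 "ci_low": re["ci_low"], "ci_high": re["ci_high"],
                 "tau2": re["tau2"], "q_stat": re["q_stat"]}
            )
            pd.DataFrame(rows).to_csv(
                os.path.join(out_dir, f"forest_{name}_{kind}.tsv"), sep="\t", index=False
            )
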