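"""Common-attention estimation and subtraction (the group-residual pipeline)."""

import numpy as np
import pytest

from visattn.gaze_io import AttentionMap, Group, MapKind
from visattn.heatmap import normalize_map
from visattn.preprocess import (
    CommonAttention,
    GroupAverage,
    common_attention,
    preprocess_group,
    subtract_common,
)
from visattn.synthetic import gen_fixations, gen_stimuli

from conftest import make_sequence


def ga(values, group=Group.CLINICIAN, sid="s1", n=3):
    return GroupAverage(group=group, stimulus_id=sid,
                        map=normalize_map(AttentionMap(np.asarray(values, float))), n_participants=n)


class TestCommonAttention:
    def test_identical_maps_yield_that_map(self, rng):
        vals = rng.random((6, 6)) + 0.01
        avgs = [ga(vals, sid=f"s{i}") for i in range(4)]
        common = common_attention(avgs)
        assert np.allclose(common.map.values, vals / vals.sum())
        assert common.n_stimuli == 4 and common.group is Group.CLINICIAN

    def test_disjoint_hotspots_average_at_half_intensity(self):
        a = np.zeros((4, 4)); a[0, 0] = 2.0
        b = np.zeros((4, 4)); b[3, 3] = 5.0
        common = common_attention([ga(a, sid="s1"), ga(b, sid="s2")])
        assert common.map.values[0, 0] == pytest.approx(0.5)
        assert common.map.values[3, 3] == pytest.approx(0.5)

    def test_mixed_groups_rejected(self, rng):
        avgs = [ga(rng.random((3, 3)), group=Group.CLINICIAN),
                ga(rng.random((3, 3)), group=Group.NON_CLINICIAN)]
        with pytest.raises(ValueError, match="[Mm]ixed"):
            common_attention(avgs)

    def test_common_map_peaks_at_planted_face_components(self, default_cohort):
        """Averaged over 16 stimuli, the common pattern's main modes sit at
        the three shared eyes/nose/mouth component centers."""
        cfg, stimuli, sequences, _ = default_cohort
        from visattn.preprocess import group_averages

        clin = [s for s in sequences if s.group is Group.CLINICIAN]
        avgs = group_averages(clin, Group.CLINICIAN, cfg.image_px, cfg.image_px)
        common = common_attention(list(avgs.values()))
        vals = common.map.values.copy()
        centers = [c.center_xy for c in stimuli[0].common_profile.components]
        found = []
        for _ in range(3):  # greedy top-3 local maxima with suppression
            y, x = np.unravel_index(vals.argmax(), vals.shape)
            found.append((x, y))
            yy, xx = np.mgrid[0: vals.shape[0], 0: vals.shape[1]]
            vals[np.hypot(xx - x, yy - y) < 0.12 * cfg.image_px] = 0
        for cx, cy in centers:
            assert min(np.hypot(fx - cx, fy - cy) for fx, fy in found) < 0.1 * cfg.image_px


class TestSubtractCommon:
    def test_map_equal_to_common_leaves_zero_residual(self, rng):
        vals = rng.random((5, 5)) + 0.01
        avg = ga(vals)
        common = CommonAttention(Group.CLINICIAN, normalize_map(AttentionMap(vals)), 4)
        residual = subtract_common(avg, common)
        assert residual.kind is MapKind.DIFFERENCE
        assert np.allclose(residual.values, 0)

    def test_single_cell_surplus_is_recovered(self):
        base = np.full((4, 4), 1.0)
        common = CommonAttention(Group.CLINICIAN, normalize_map(AttentionMap(base)), 4)
        bumped = common.map.values.copy()
        delta = 0.03
        bumped[2, 1] += delta
        avg = GroupAverage(Group.CLINICIAN, "s1", AttentionMap(bumped), 3)
        residual = subtract_common(avg, common)
        assert residual.values[2, 1] == pytest.approx(delta)
        mask = np.ones_like(base, bool); mask[2, 1] = False
        assert np.allclose(residual.values[mask], 0)

    def test_group_mismatch_rejected(self, rng):
        vals = rng.random((3, 3)) + 0.01
        avg = ga(vals, group=Group.CLINICIAN)
        common = CommonAttention(Group.NON_CLINICIAN, normalize_map(AttentionMap(vals)), 2)
        with pytest.raises(ValueError, match="mismatch"):
            subtract_common(avg, common)

    def test_residual_bounded_by_input_and_nonnegative(self, rng):
        for _ in range(10):
            a = rng.random((6, 6)) + 0.01
            c = rng.random((6, 6)) + 0.01
            avg = ga(a)
            common = CommonAttention(Group.CLINICIAN, normalize_map(AttentionMap(c)), 3)
            res = subtract_common(avg, common)
            assert (res.values >= 0).all()
            assert (res.values <= avg.map.values + 1e-15).all()


class TestPreprocessGroup:
    def test_single_participant_single_stimulus_residual_is_zero(self):
        seq = make_sequence([(20, 20, 0, 100), (40, 30, 200, 150)])
        out = preprocess_group([seq], Group.CLINICIAN, 64, 64)
        assert set(out) == {"s1"}
        assert np.allclose(out["s1"].values, 0)  # common equals the only map

    def test_identical_gaze_on_two_stimuli_residuals_zero(self):
        pts = [(20, 20, 0, 100), (40, 30, 200, 150)]
        seqs = [make_sequence(pts, stimulus="s1"), make_sequence(pts, stimulus="s2")]
        out = preprocess_group(seqs, Group.CLINICIAN, 64, 64)
        for sid in ("s1", "s2"):
            assert np.allclose(out[sid].values, 0, atol=1e-15)

    def test_participant_order_invariance(self, small_cohort):
        cfg, _, sequences, _ = small_cohort
        clin = [s for s in sequences if s.group is Group.CLINICIAN]
        a = preprocess_group(clin, Group.CLINICIAN, cfg.image_px, cfg.image_px)
        b = preprocess_group(clin[::-1], Group.CLINICIAN, cfg.image_px, cfg.image_px)
        assert set(a) == set(b)
        for sid in a:
            assert np.allclose(a[sid].values, b[sid].values)

    def test_other_group_sequences_ignored(self, small_cohort):
        cfg, _, sequences, _ = small_cohort
        clin = [s for s in sequences if s.group is Group.CLINICIAN]
        a = preprocess_group(clin, Group.CLINICIAN, cfg.image_px, cfg.image_px)
        b = preprocess_group(sequences, Group.CLINICIAN, cfg.image_px, cfg.image_px)
        for sid in a:
            assert np.allclose(a[sid].values, b[sid].values)

    def test_per_participant_subtraction_variant(self, small_cohort):
        """Subtracting before vs after averaging differs (clipping is
        nonlinear) but both localize the same planted features."""
        cfg, stimuli, sequences, _ = small_cohort
        clin = [s for s in sequences if s.group is Group.CLINICIAN]
        at_avg = preprocess_group(clin, Group.CLINICIAN, cfg.image_px, cfg.image_px)
        per_p = preprocess_group(
            clin, Group.CLINICIAN, cfg.image_px, cfg.image_px, per_participant=True
        )
        assert set(at_avg) == set(per_p)
        for sid in at_avg:
            assert (per_p[sid].values >= 0).all()
            a = np.unravel_index(at_avg[sid].values.argmax(), at_avg[sid].shape)
            b = np.unravel_index(per_p[sid].values.argmax(), per_p[sid].shape)
            assert np.hypot(a[0] - b[0], a[1] - b[1]) < 0.15 * cfg.image_px

    def test_residuals_recover_planted_feature_locations(self, default_cohort):
        """Full-scale recovery: clinician residual argmax falls inside the
        planted stimulus-specific component's support on >= 14/16 stimuli."""
        cfg, stimuli, sequences, _ = default_cohort
        clin = [s for s in sequences if s.group is Group.CLINICIAN]
        residuals = preprocess_group(clin, Group.CLINICIAN, cfg.image_px, cfg.image_px)
        hits = 0
        for stim in stimuli:
            res = residuals[stim.stimulus_id]
            y, x = np.unravel_index(res.values.argmax(), res.shape)
            comp = stim.specific_profiles[Group.CLINICIAN].components[0]
            if np.hypot(x - comp.center_xy[0], y - comp.center_xy[1]) <= 3 * comp.sd_px:
                hits += 1
        assert hits >= 14
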