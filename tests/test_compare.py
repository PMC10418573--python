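"""Binarization, IoU, bootstrap uncertainty and random-effects pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from visattn.compare import (
    EffectEstimate,
    ThresholdKind,
    binarize,
    bootstrap_iou,
    iou,
    re_meta_analysis,
)
from visattn.gaze_io import AttentionMap, MapKind


def bmap(mask, kind=ThresholdKind.LOW):
    from visattn.compare import BinaryMap
    return BinaryMap(np.asarray(mask, bool), threshold_kind=kind, source_kind=MapKind.GAZE)


class TestBinarize:
    def test_all_zero_map_gives_empty_masks(self):
        amap = AttentionMap(np.zeros((5, 5)))
        for kind in ThresholdKind:
            assert binarize(amap, kind).area() == 0

    def test_integer_grid_quantile_threshold(self):
        # nonzero values 1..100: the 0.75-quantile threshold keeps 76..100
        vals = np.concatenate([np.zeros(28), np.arange(1, 101)]).reshape(8, 16)
        mask = binarize(AttentionMap(vals), ThresholdKind.HIGH, q_high=0.75)
        kept = vals[mask.mask]
        assert kept.min() == 76 and kept.max() == 100 and mask.area() == 25

    def test_high_mask_subset_of_low_mask(self, rng):
        for _ in range(10):
            amap = AttentionMap(rng.random((12, 12)) * (rng.random((12, 12)) > 0.4))
            low = binarize(amap, ThresholdKind.LOW)
            high = binarize(amap, ThresholdKind.HIGH)
            assert not np.any(high.mask & ~low.mask)

    @settings(deadline=None, max_examples=30)
    @given(q1=st.floats(0.05, 0.9), q2=st.floats(0.05, 0.9))
    def test_raising_quantile_never_grows_mask(self, q1, q2):
        qa, qb = sorted((q1, q2))
        vals = np.random.default_rng(99).random((10, 10))
        a = binarize(AttentionMap(vals), ThresholdKind.LOW, q_low=qa)
        b = binarize(AttentionMap(vals), ThresholdKind.LOW, q_low=qb)
        assert not np.any(b.mask & ~a.mask)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.2, 1.7])
    def test_quantile_outside_unit_interval_rejected(self, q):
        with pytest.raises(ValueError):
            binarize(AttentionMap(np.ones((3, 3))), ThresholdKind.LOW, q_low=q, q_high=0.5)


class TestIoU:
    def test_identical_nonempty_masks_score_one(self, rng):
        m = rng.random((9, 9)) > 0.5
        assert iou(bmap(m), bmap(m)) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4), bool); a[0] = True
        b = np.zeros((4, 4), bool); b[3] = True
        assert iou(bmap(a), bmap(b)) == 0.0

    def test_overlapping_row_bands_score_one_third(self):
        a = np.zeros((3, 5), bool); a[0:2] = True
        b = np.zeros((3, 5), bool); b[1:3] = True
        assert iou(bmap(a), bmap(b)) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            assert iou(bmap(np.zeros((3, 3))), bmap(np.zeros((3, 3)))) == 0.0

    def test_dimension_and_kind_mismatches_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            iou(bmap(np.ones((3, 3))), bmap(np.ones((4, 3))))
        with pytest.raises(ValueError, match="kind"):
            iou(bmap(np.ones((3, 3)), ThresholdKind.LOW),
                bmap(np.ones((3, 3)), ThresholdKind.HIGH))

    @settings(deadline=None, max_examples=40)
    @given(
        a=arrays(bool, (6, 6), elements=st.booleans()),
        b=arrays(bool, (6, 6), elements=st.booleans()),
    )
    def test_symmetry_range_and_self_identity(self, a, b):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ab, ba = iou(bmap(a), bmap(b)), iou(bmap(b), bmap(a))
        assert ab == ba and 0.0 <= ab <= 1.0
        if a.any():
            assert iou(bmap(a), bmap(a)) == 1.0

    def test_matches_brute_force_cell_count(self, rng):
        for _ in range(5):
            a = rng.random((20, 20)) > 0.6
            b = rng.random((20, 20)) > 0.6
            inter = sum(a[y, x] and b[y, x] for y in range(20) for x in range(20))
            union = sum(a[y, x] or b[y, x] for y in range(20) for x in range(20))
            assert iou(bmap(a), bmap(b)) == pytest.approx(inter / union)


class TestBootstrapIoU:
    def test_single_identical_participant_degenerate(self, rng):
        m = AttentionMap(rng.random((10, 10)) + 0.01)
        est = bootstrap_iou([m], [m], ThresholdKind.LOW, n_boot=50, seed=0)
        assert est.effect == 1.0 and est.se == 0.0

    def test_same_group_both_sides_scores_one(self, rng):
        maps = [AttentionMap(rng.random((10, 10)) + 0.01) for _ in range(5)]
        est = bootstrap_iou(maps, maps, ThresholdKind.HIGH, n_boot=50, seed=1)
        assert est.effect == 1.0

    def test_seed_reproducibility(self, rng):
        a = [AttentionMap(rng.random((12, 12)) + 0.01) for _ in range(6)]
        b = [AttentionMap(rng.random((12, 12)) + 0.01) for _ in range(6)]
        e1 = bootstrap_iou(a, b, ThresholdKind.LOW, n_boot=80, seed=42)
        e2 = bootstrap_iou(a, b, ThresholdKind.LOW, n_boot=80, seed=42)
        assert (e1.effect, e1.se) == (e2.effect, e2.se)

    def test_se_stable_across_seeds(self, rng):
        """Bootstrap SD is an estimate: two seeds agree within 20% relative."""
        a = [AttentionMap(rng.random((16, 16)) + 0.05) for _ in range(10)]
        b = [AttentionMap(rng.random((16, 16)) + 0.05) for _ in range(10)]
        e0 = bootstrap_iou(a, b, ThresholdKind.LOW, n_boot=1000, seed=0)
        e1 = bootstrap_iou(a, b, ThresholdKind.LOW, n_boot=1000, seed=1)
        assert e0.effect == e1.effect  # point estimate does not depend on seed
        assert abs(e0.se - e1.se) <= 0.2 * max(e0.se, e1.se)

    def test_too_few_replicates_rejected(self, rng):
        m = [AttentionMap(rng.random((5, 5)) + 0.01)]
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_iou(m, m, ThresholdKind.LOW, n_boot=1)


class TestREMetaAnalysis:
    def test_homogeneous_effects_pool_exactly(self):
        effects = [EffectEstimate(f"s{i}", 0.42, 0.05) for i in range(6)]
        res = re_meta_analysis(effects)
        assert res.pooled_effect == pytest.approx(0.42)
        assert res.tau2 == 0.0 and res.q_stat == pytest.approx(0.0)
        assert res.ci_low < 0.42 < res.ci_high

    def test_symmetric_pair_pools_to_midpoint(self):
        effects = [EffectEstimate("a", 0.4, 0.1), EffectEstimate("b", 0.6, 0.1)]
        assert re_meta_analysis(effects).pooled_effect == pytest.approx(0.5)

    def test_single_stimulus_rejected(self):
        with pytest.raises(ValueError, match="2"):
            re_meta_analysis([EffectEstimate("a", 0.4, 0.1)])

    def test_zero_se_floored_with_warning(self):
        effects = [EffectEstimate("a", 0.4, 0.0), EffectEstimate("b", 0.6, 0.1)]
        with pytest.warns(UserWarning, match="floored"):
            res = re_meta_analysis(effects)
        assert np.isfinite(res.pooled_effect)

    def test_tau2_zero_reduces_to_fixed_effect(self, rng):
        """With homogeneous data (tau2 estimates 0), DL pooling equals the
        fixed-effect inverse-variance estimate to 1e-12."""
        se = rng.uniform(0.02, 0.2, size=8)
        y = np.full(8, 0.37)  # no heterogeneity at all
        effects = [EffectEstimate(f"s{i}", float(y[i]), float(se[i])) for i in range(8)]
        res = re_meta_analysis(effects)
        assert res.tau2 == 0.0
        w = 1 / se**2
        fixed = float((w * y).sum() / w.sum())
        assert abs(res.pooled_effect - fixed) < 1e-12

    def test_matches_statsmodels_dersimonian_laird(self, rng):
        """Independent oracle: statsmodels' DL estimator on random effects."""
        from statsmodels.stats.meta_analysis import combine_effects

        y = rng.uniform(0.2, 0.8, size=10)
        se = rng.uniform(0.03, 0.15, size=10)
        effects = [EffectEstimate(f"s{i}", float(y[i]), float(se[i])) for i in range(10)]
        res = re_meta_analysis(effects)
        sm = combine_effects(y, se**2, method_re="chi2")  # DL moment estimator
        assert res.tau2 == pytest.approx(float(sm.tau2), rel=1e-8, abs=1e-12)
        assert res.pooled_effect == pytest.approx(
            float(sm.mean_effect_re), rel=1e-8
        )

    def test_pooled_estimate_calibrated_against_true_uncertainty(self):
        """The pooled estimator is well calibrated against its *true*
        standard error (computed from the known se and true tau): the
        standardized error behaves like a standard normal."""
        zs = []
        for seed in range(100):
            g = np.random.default_rng(seed)
            se = g.uniform(0.03, 0.08, size=16)
            theta = g.normal(0.45, 0.05, size=16)
            y = g.normal(theta, se)
            effects = [
                EffectEstimate(f"s{i}", float(np.clip(y[i], 0, 1)), float(se[i]))
                for i in range(16)
            ]
            res = re_meta_analysis(effects)
            se_true = float(np.sum(1.0 / (se**2 + 0.05**2)) ** -0.5)
            zs.append((res.pooled_effect - 0.45) / se_true)
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.3  # unbiased
        assert 0.7 < zs.std() < 1.3  # unit-scale standardized errors
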