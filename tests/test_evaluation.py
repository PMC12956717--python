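import numpy as np
import pytest

from ctquant import evaluation as ev
from ctquant.core import CTVolume, LabelMask


class TestDiceIoU:
    def test_identical_masks_are_perfect(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[:2] = True
        res = ev.dice_iou(m, m)
        assert (res.dice, res.iou) == (1.0, 1.0) and not res.flags

    def test_disjoint_masks_are_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0], b[3] = True, True
        res = ev.dice_iou(a, b)
        assert (res.dice, res.iou) == (0.0, 0.0)

    def test_half_overlap_hand_values(self):
        a = np.zeros((8,), dtype=bool).reshape(2, 2, 2)
        b = a.copy()
        a.ravel()[:4] = True
        b.ravel()[2:6] = True  # |A|=|B|=4, intersection 2
        res = ev.dice_iou(a, b)
        assert res.dice == pytest.approx(0.5)
        assert res.iou == pytest.approx(1 / 3)

    def test_both_empty_is_perfect_but_flagged(self):
        res = ev.dice_iou(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 2), bool))
        assert (res.dice, res.iou) == (1.0, 1.0) and res.flags

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            ev.dice_iou(np.zeros((2, 2, 2), bool), np.zeros((2, 2, 3), bool))

    def test_dice_iou_identity_over_1000_random_pairs(self, rng):
        """dice = 2*iou/(1+iou) on every random mask pair."""
        for _ in range(1000):
            a = rng.random((6, 6, 6)) < rng.uniform(0.05, 0.9)
            b = rng.random((6, 6, 6)) < rng.uniform(0.05, 0.9)
            res = ev.dice_iou(a, b)
            assert res.dice == pytest.approx(2 * res.iou / (1 + res.iou), abs=1e-12)


class TestRegressionAgreement:
    def test_identity_series(self):
        res = ev.regression_agreement([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.rmse == 0.0

    def test_affine_invariance_of_correlation(self):
        ref = np.array([1.0, 2.0, 5.0, 7.0])
        res = ev.regression_agreement(2 * ref + 1, ref)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.rmse > 0

    def test_reversed_series_hand_values(self):
        res = ev.regression_agreement([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.rmse == pytest.approx(np.sqrt(8 / 3))

    def test_zero_variance_flagged_undefined(self):
        res = ev.regression_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.pearson_r is None and res.spearman_rho is None
        assert res.rmse is not None and res.flags

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ev.regression_agreement([1.0, 2.0], [1.0, 2.0])


class TestLosses:
    def test_perfect_prediction_has_near_zero_loss(self):
        g = np.zeros((4, 4, 4), dtype=bool)
        g[:2] = True
        assert ev.soft_dice_loss(g.astype(float), g) == pytest.approx(0.0, abs=1e-6)

    def test_inverted_prediction_has_near_unit_loss(self):
        g = np.zeros((4, 4, 4), dtype=bool)
        g[:2] = True
        assert ev.soft_dice_loss(1.0 - g.astype(float), g) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_half_probability_closed_form(self):
        g = np.zeros((4, 4, 4), dtype=bool)
        g[:2] = True
        assert ev.soft_dice_loss(np.full(g.shape, 0.5), g) == pytest.approx(0.5, abs=1e-6)

    def test_soft_dice_on_hard_masks_equals_one_minus_dice(self, rng):
        for _ in range(50):
            a = rng.random((5, 5, 5)) < 0.4
            b = rng.random((5, 5, 5)) < 0.4
            if not (a.sum() + b.sum()):
                continue
            loss = ev.soft_dice_loss(a.astype(float), b)
            dice = ev.dice_iou(a, b).dice
            assert loss == pytest.approx(1 - dice, abs=1e-5)

    def test_out_of_range_probabilities_rejected(self):
        g = np.zeros((2, 2, 2), dtype=bool)
        with pytest.raises(ValueError):
            ev.soft_dice_loss(np.full(g.shape, 1.5), g)

    def test_combined_loss_reduces_to_components(self):
        g = np.zeros((4, 4, 4), dtype=bool)
        g[:1] = True
        p = np.full(g.shape, 0.5)
        dice_term = ev.soft_dice_loss(p, g)
        assert ev.combined_loss([(p, g)], mse_weight=0.0) == pytest.approx(dice_term)
        assert ev.combined_loss(reg_pred=[1.0, 2.0], reg_target=[0.0, 0.0],
                                seg_weight=0.0) == pytest.approx(2.5)

    def test_perfect_both_heads_is_global_minimum(self):
        g = np.zeros((4, 4, 4), dtype=bool)
        g[:2] = True
        loss = ev.combined_loss([(g.astype(float), g)], reg_pred=[1.0, 2.0],
                                reg_target=[1.0, 2.0])
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            ev.combined_loss(seg_weight=-1.0)


class TestSplits:
    def test_single_stratum_100_items(self):
        s = ev.make_splits(list(range(100)), ev.SplitPlan(seed=0))
        assert (len(s.train), len(s.val), len(s.test)) == (70, 15, 15)

    def test_partition_is_disjoint_and_exhaustive(self):
        items = [f"s{i}" for i in range(40)]
        strata = [i % 4 for i in range(40)]
        s = ev.make_splits(items, ev.SplitPlan(seed=5), strata)
        combined = s.train + s.val + s.test
        assert sorted(combined) == sorted(items)
        assert len(set(combined)) == len(items)
        fold_union = [it for f in s.folds for it in f]
        assert sorted(fold_union) == sorted(items)

    def test_four_strata_of_five_give_one_per_stratum_per_fold(self):
        items = list(range(20))
        strata = [i % 4 for i in items]
        s = ev.make_splits(items, ev.SplitPlan(seed=1, k=5), strata)
        for fold in s.folds:
            assert len(fold) == 4
            assert sorted(i % 4 for i in fold) == [0, 1, 2, 3]

    def test_deterministic_under_seed(self):
        items = list(range(50))
        a = ev.make_splits(items, ev.SplitPlan(seed=9))
        b = ev.make_splits(items, ev.SplitPlan(seed=9))
        assert a.train == b.train and a.folds == b.folds

    def test_stratum_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="< k"):
            ev.make_splits(list(range(8)), ev.SplitPlan(seed=0, k=5),
                           strata=[0] * 4 + [1] * 4)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ev.SplitPlan(fractions=(0.5, 0.2, 0.2))


class TestAugment:
    @staticmethod
    def _pair(shape=(16, 24, 24)):
        rng = np.random.default_rng(0)
        vol = CTVolume(rng.normal(-500, 100, shape))
        mask = np.zeros(shape, dtype=np.int16)
        mask[4:12, 8:16, 8:16] = 1
        return vol, LabelMask(mask)

    def test_identity_config_returns_input_unchanged(self):
        vol, mask = self._pair()
        cfg = ev.AugmentConfig(rotation_deg=0.0, flip_horizontal=False,
                               flip_vertical=False, crop_scale=(1.0, 1.0),
                               intensity_amplitude_hu=0.0, seed=1)
        out_v, out_m = ev.augment(vol, mask, cfg)
        assert np.array_equal(out_v.data, vol.data)
        assert np.array_equal(out_m.data, mask.data)

    def test_same_seed_reproduces_transform(self):
        vol, mask = self._pair()
        cfg = ev.AugmentConfig(seed=7, intensity_amplitude_hu=25.0)
        a_v, a_m = ev.augment(vol, mask, cfg)
        b_v, b_m = ev.augment(vol, mask, cfg)
        assert np.array_equal(a_v.data, b_v.data)
        assert np.array_equal(a_m.data, b_m.data)

    def test_rotation_of_sphere_mask_keeps_high_overlap(self):
        shape = (16, 32, 32)
        z, y, x = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        sphere = ((z - 8) ** 2 + (y - 16) ** 2 + (x - 16) ** 2) <= 64
        vol = CTVolume(np.where(sphere, 0.0, -850.0))
        mask = LabelMask(sphere.astype(np.int16))
        cfg = ev.AugmentConfig(rotation_deg=10.0, flip_horizontal=False,
                               flip_vertical=False, crop_scale=(1.0, 1.0), seed=3)
        _, out_m = ev.augment(vol, mask, cfg)
        res = ev.dice_iou(out_m.data > 0, sphere)
        assert res.dice >= 0.95

    def test_crop_scale_bounds_validated(self):
        with pytest.raises(ValueError):
            ev.AugmentConfig(crop_scale=(0.0, 1.0))
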