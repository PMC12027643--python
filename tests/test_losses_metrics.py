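"""Closed-form checks of the BceDice objective and the five pixel metrics."""

import numpy as np
import pytest

from mgraunet import (
    ConfusionCounts,
    LossConfig,
    bce_dice_loss,
    confusion,
    evaluate_masks,
    metrics,
)


class TestBceDice:
    def test_perfect_prediction_gives_near_zero_loss(self):
        gt = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert bce_dice_loss(gt.copy(), gt) < 1e-5

    def test_uniform_half_prediction_bce_is_ln2(self):
        gt = np.array([1.0, 1.0, 0.0, 0.0])
        pred = np.full(4, 0.5)
        # Dice term: 1 - (2*1 + eps)/(2 + 2 + eps) = 0.5
        total = bce_dice_loss(pred, gt)
        assert abs(total - (np.log(2) + 0.5)) < 1e-6

    def test_four_pixel_hand_calculation(self):
        y = np.array([1.0, 1.0, 0.0, 0.0])
        p = np.array([0.9, 0.6, 0.2, 0.1])
        eps = 1e-6
        bce = -(np.log(0.9) + np.log(0.6) + np.log(0.8) + np.log(0.9)) / 4
        dice = 1.0 - (2 * (0.9 + 0.6) + eps) / (p.sum() + 2.0 + eps)
        got = bce_dice_loss(p, y, LossConfig(epsilon=eps))
        assert abs(got - (bce + dice)) < 1e-9

    def test_alpha_beta_weighting(self):
        y = np.array([1.0, 0.0])
        p = np.array([0.7, 0.4])
        b = bce_dice_loss(p, y, LossConfig(alpha=1, beta=0))
        d = bce_dice_loss(p, y, LossConfig(alpha=0, beta=1))
        both = bce_dice_loss(p, y, LossConfig(alpha=2, beta=3))
        assert abs(both - (2 * b + 3 * d)) < 1e-9

    def test_empty_masks_stay_finite(self):
        y = np.zeros(8)
        p = np.zeros(8)
        assert np.isfinite(bce_dice_loss(p, y))

    def test_shape_mismatch_and_nonbinary_gt_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            bce_dice_loss(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError, match="binary"):
            bce_dice_loss(np.zeros(3), np.full(3, 0.5))

    def test_loss_never_increases_as_prediction_approaches_truth(self, rng):
        """Moving any single prediction strictly closer to its label cannot
        increase the compound loss."""
        for _ in range(200):
            n = int(rng.integers(2, 9))
            y = (rng.random(n) < 0.5).astype(float)
            if y.sum() == 0:
                y[0] = 1.0
            p = rng.uniform(0.01, 0.99, size=n)
            i = int(rng.integers(n))
            p2 = p.copy()
            p2[i] = p[i] + (y[i] - p[i]) * rng.uniform(0.1, 0.9)
            assert bce_dice_loss(p2, y) <= bce_dice_loss(p, y) + 1e-12


class TestConfusion:
    def test_identical_masks_have_no_errors(self, rng):
        m = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        c = confusion(m, m)
        assert c.fp == 0 and c.fn == 0 and c.tp == int(m.sum())

    def test_complementary_masks_have_no_agreement(self, rng):
        m = (rng.random((10, 10)) < 0.3).astype(np.uint8)
        c = confusion(1 - m, m)
        assert c.tp == 0 and c.tn == 0

    def test_counts_match_per_pixel_double_loop(self, rng):
        pred = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        gt = (rng.random((10, 10)) < 0.4).astype(np.uint8)
        tp = fp = tn = fn = 0
        for i in range(10):
            for j in range(10):
                if pred[i, j] and gt[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif gt[i, j]:
                    fn += 1
                else:
                    tn += 1
        c = confusion(pred, gt)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert c.total == 100

    def test_nonbinary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion(np.full((2, 2), 0.5), np.zeros((2, 2)))


class TestMetrics:
    def test_worked_confusion_example(self):
        r = metrics(ConfusionCounts(tp=6, fp=2, tn=90, fn=2))
        assert (r.acc, r.dsc, r.pre, r.rec, r.iou) == (0.96, 0.75, 0.75, 0.75, 0.6)

    def test_both_empty_convention(self):
        r = metrics(ConfusionCounts(tp=0, fp=0, tn=50, fn=0))
        assert (r.acc, r.dsc, r.iou, r.pre, r.rec) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_no_true_positive_with_errors_scores_zero(self):
        r = metrics(ConfusionCounts(tp=0, fp=3, tn=90, fn=7))
        assert r.dsc == 0.0 and r.iou == 0.0

    def test_dsc_iou_identity_on_random_tables(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 1000, size=4)
            if tp + fp + fn == 0:
                tp = 1
            r = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert abs(r.dsc - 2 * r.iou / (1 + r.iou)) < 1e-12

    def test_metrics_invariant_under_joint_permutation(self, rng):
        pred = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        gt = (rng.random((8, 8)) < 0.4).astype(np.uint8)
        perm = rng.permutation(64)
        r1 = metrics(confusion(pred, gt))
        r2 = metrics(confusion(pred.ravel()[perm], gt.ravel()[perm]))
        assert r1 == r2

    def test_dataset_mean_averages_per_image(self, rng):
        preds = [np.ones((4, 4), np.uint8), np.zeros((4, 4), np.uint8)]
        gts = [np.ones((4, 4), np.uint8), np.ones((4, 4), np.uint8)]
        reports, mean = evaluate_masks(preds, gts)
        assert reports[0].dsc == 1.0 and reports[1].dsc == 0.0
        assert mean.dsc == 0.5
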