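"""Tversky/Dice/PCC losses, confusion counts, HD95, per-case evaluation."""

import numpy as np
import pytest

from ctvkit import (
    BinaryMask, ConfusionCounts, VolumeGrid, confusion_counts, dice,
    evaluate_pair, hd95, pcc_score, size_adaptive_params, tversky_index,
)
from ctvkit.metrics import (
    bce_loss_grad, compound_loss_grad, soft_dice_loss_grad,
    soft_tversky_loss_grad,
)

from conftest import brute_force_hd95, random_blob


def mask(vals, spacing=(3, 3, 3)):
    return BinaryMask.from_spacing(np.asarray(vals), spacing)


class TestConfusion:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        t = mask(random_blob(rng, (6, 6, 6)))
        c = confusion_counts(t, t, mask(np.ones((6, 6, 6))))
        assert c.fp == 0 and c.fn == 0
        assert c.tp == t.n_voxels

    def test_hand_counted_fixture(self):
        pred = np.zeros((4, 4, 4))
        truth = np.zeros((4, 4, 4))
        truth[0, 0, :4] = 1          # 4 truth voxels
        pred[0, 0, :3] = 1           # 3 TP, 1 FN
        pred[1, 1, :2] = 1           # 2 FP
        c = confusion_counts(mask(pred), mask(truth), mask(np.ones((4, 4, 4))))
        assert (c.tp, c.fp, c.fn) == (3, 2, 1)
        assert c.tn == 64 - 6
        assert c.total == 64

    def test_soft_degenerates_to_hard_on_binary_probs(self):
        rng = np.random.default_rng(1)
        p = random_blob(rng, (5, 5, 5)).astype(float)
        t = random_blob(rng, (5, 5, 5))
        m = np.ones((5, 5, 5), dtype=bool)
        hard = confusion_counts(mask(p), mask(t), mask(m), soft=False)
        soft = confusion_counts(VolumeGrid.from_spacing(p), mask(t), mask(m),
                                soft=True)
        for name in ("tp", "fp", "fn", "tn"):
            assert getattr(hard, name) == getattr(soft, name)

    def test_probabilities_outside_unit_interval_rejected(self):
        p = VolumeGrid.from_spacing(np.full((3, 3, 3), 1.5))
        t = mask(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            confusion_counts(p, t, t, soft=True)


class TestTversky:
    def test_half_half_is_dice_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            tp = int(rng.integers(1, 50))
            fp, fn, tn = (int(v) for v in rng.integers(0, 50, 3))
            c = ConfusionCounts(tp, fp, fn, tn)
            d = 2 * c.tp / (2 * c.tp + c.fp + c.fn)
            assert tversky_index(c, 0.5, 0.5, smooth=0.0) == \
                pytest.approx(d, rel=1e-12)

    def test_fixed_weight_fixture(self):
        # TP=8, FP=4, FN=2 at (0.02, 0.98): 8 / (8 + 0.08 + 1.96)
        c = ConfusionCounts(8, 4, 2, 100)
        assert tversky_index(c, 0.02, 0.98, smooth=0.0) == pytest.approx(
            8 / (8 + 0.08 + 1.96), rel=1e-12)

    def test_zero_tp_limit(self):
        c = ConfusionCounts(0, 3, 2, 10)
        assert tversky_index(c, 0.5, 0.5, smooth=1e-12) < 1e-9

    def test_fixture_cross_checked_against_mask_computation(self):
        pred = np.zeros((4, 4, 4))
        truth = np.zeros((4, 4, 4))
        truth[0, :3, :4] = 1            # 12 truth
        pred[0, :3, :2] = 1             # 6 TP
        pred[3, 0, :2] = 1              # 2 FP
        c = confusion_counts(mask(pred), mask(truth), mask(np.ones((4, 4, 4))))
        assert (c.tp, c.fp, c.fn) == (6, 2, 6)
        expect = (6) / (6 + 0.02 * 2 + 0.98 * 6)
        assert tversky_index(c, 0.02, 0.98, smooth=0.0) == pytest.approx(expect)


class TestSizeAdaptive:
    def test_printed_weights_at_f_002(self):
        p = size_adaptive_params(2, 100)
        assert round(p.beta, 2) == 0.98
        assert round(p.alpha, 2) == 0.02

    def test_f_one_reduces_to_dice_weighting(self):
        p = size_adaptive_params(100, 100)
        assert p.alpha == pytest.approx(0.5)
        assert p.beta == pytest.approx(0.5)

    def test_direct_arithmetic(self):
        p = size_adaptive_params(2000, 50000)
        assert p.f == pytest.approx(0.04)
        assert p.beta == pytest.approx(1 / 1.04, rel=1e-12)

    def test_beta_strictly_decreasing_and_complementary(self):
        fs = np.linspace(0, 2, 41)
        betas = [size_adaptive_params(f * 1000, 1000).beta for f in fs]
        assert all(b1 > b2 for b1, b2 in zip(betas, betas[1:]))
        for f, b in zip(fs, betas):
            assert size_adaptive_params(f * 1000, 1000).alpha + b == \
                pytest.approx(1.0)

    def test_zero_brain_rejected(self):
        with pytest.raises(ValueError):
            size_adaptive_params(10, 0)


class TestPCC:
    def test_perfect_and_disjoint_limits(self):
        rng = np.random.default_rng(3)
        t = mask(random_blob(rng, (6, 6, 6), p_fg=0.2))
        brain = mask(np.ones((6, 6, 6)))
        assert pcc_score(t, t, brain, t) == pytest.approx(1.0, abs=1e-6)
        disjoint = np.zeros((6, 6, 6))
        disjoint[5, 5, 5] = 1
        disjoint = mask(disjoint * ~t.values)
        assert pcc_score(disjoint, t, brain, t, smooth=1e-12) < 1e-9

    def test_small_lesions_punish_misses_harder(self):
        """Same confusion counts, smaller f => larger beta => lower score."""
        c = ConfusionCounts(50, 10, 20, 1000)
        small = size_adaptive_params(10, 1000)
        large = size_adaptive_params(100, 1000)
        assert tversky_index(c, small.alpha, small.beta) < \
            tversky_index(c, large.alpha, large.beta)

    def test_composition_with_confusion_counts(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            pred = mask(random_blob(rng, (6, 6, 6)))
            t = mask(random_blob(rng, (6, 6, 6)))
            brain = mask(random_blob(rng, (6, 6, 6), p_fg=0.9))
            score = pcc_score(pred, t, brain, t)
            params = size_adaptive_params(t.n_voxels, brain.n_voxels)
            c = confusion_counts(pred, t, brain)
            assert score == pytest.approx(
                tversky_index(c, params.alpha, params.beta), rel=1e-12)

    def test_empty_lesion_reference_rejected(self):
        z = mask(np.zeros((3, 3, 3)))
        o = mask(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            pcc_score(o, o, o, z)


class TestSoftLossGradients:
    @staticmethod
    def _fd_check(loss_fn, p, seed, tol=1e-4):
        rng = np.random.default_rng(seed)
        loss, grad = loss_fn(p)
        for _ in range(5):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-6
            p1 = p.copy(); p1[idx] += eps
            p0 = p.copy(); p0[idx] -= eps
            fd = (loss_fn(p1)[0] - loss_fn(p0)[0]) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, abs=tol, rel=1e-3)

    def test_tversky_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        t = random_blob(rng, (6, 6, 6)).astype(float)
        m = random_blob(rng, (6, 6, 6), p_fg=0.9)
        p = rng.uniform(0.05, 0.95, (6, 6, 6))
        self._fd_check(lambda q: soft_tversky_loss_grad(q, t, m, 0.02, 0.98),
                       p, seed=6)

    def test_bce_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        t = random_blob(rng, (6, 6, 6)).astype(float)
        m = random_blob(rng, (6, 6, 6), p_fg=0.9)
        p = rng.uniform(0.05, 0.95, (6, 6, 6))
        self._fd_check(lambda q: bce_loss_grad(q, t, m), p, seed=8, tol=1e-3)

    def test_compound_loss_linearity_in_lambda(self):
        rng = np.random.default_rng(9)
        t = random_blob(rng, (6, 6, 6)).astype(float)
        m = np.ones((6, 6, 6), dtype=bool)
        p = rng.uniform(0.05, 0.95, (6, 6, 6))
        n_lesion = max(int(t.sum()), 1)
        l0, _ = compound_loss_grad(p, t, m, n_lesion, bce_weight=0.0)
        l05, _ = compound_loss_grad(p, t, m, n_lesion, bce_weight=0.5)
        l1, _ = compound_loss_grad(p, t, m, n_lesion, bce_weight=1.0)
        bce, _ = bce_loss_grad(p, t, m)
        assert l1 - l05 == pytest.approx(0.5 * bce, rel=1e-9)
        assert l05 - l0 == pytest.approx(0.5 * bce, rel=1e-9)

    def test_bce_matches_hand_computation(self):
        p = np.array([[[0.8, 0.3]]])
        t = np.array([[[1.0, 0.0]]])
        m = np.ones_like(p, dtype=bool)
        loss, _ = bce_loss_grad(p, t, m)
        hand = -(np.log(0.8) + np.log(0.7)) / 2
        assert loss == pytest.approx(hand, rel=1e-9)

    def test_pure_pcc_loss_zero_at_perfect_prediction(self):
        rng = np.random.default_rng(10)
        t = random_blob(rng, (6, 6, 6)).astype(float)
        m = np.ones((6, 6, 6), dtype=bool)
        loss, _ = compound_loss_grad(t, t, m, max(int(t.sum()), 1),
                                     bce_weight=0.0)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_dice_loss_is_tversky_half(self):
        rng = np.random.default_rng(11)
        t = random_blob(rng, (5, 5, 5)).astype(float)
        m = np.ones((5, 5, 5), dtype=bool)
        p = rng.uniform(0, 1, (5, 5, 5))
        assert soft_dice_loss_grad(p, t, m)[0] == pytest.approx(
            soft_tversky_loss_grad(p, t, m, 0.5, 0.5)[0], rel=1e-12)


class TestHD95:
    def test_identical_masks(self):
        rng = np.random.default_rng(12)
        a = mask(random_blob(rng, (8, 8, 8)))
        assert hd95(a, a) == 0.0

    def test_two_point_case(self):
        a = np.zeros((9, 9, 9)); a[1, 4, 4] = 1
        b = np.zeros((9, 9, 9)); b[5, 4, 4] = 1
        assert hd95(mask(a), mask(b)) == pytest.approx(12.0)  # 4 vox * 3 mm

    def test_empty_mask_rejected(self):
        a = mask(np.zeros((4, 4, 4)))
        b = mask(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            hd95(a, b)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        spacing = tuple(rng.uniform(1, 4, 3).round(2))
        a = random_blob(rng, (12, 12, 12), p_fg=0.2)
        b = random_blob(rng, (12, 12, 12), p_fg=0.2)
        got = hd95(mask(a, spacing), mask(b, spacing))
        assert got == pytest.approx(brute_force_hd95(a, b, spacing), rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(13)
        a = mask(random_blob(rng, (10, 10, 10)))
        b = mask(random_blob(rng, (10, 10, 10)))
        assert hd95(a, b) == pytest.approx(hd95(b, a))


class TestEvaluatePair:
    def test_perfect_ctv(self):
        rng = np.random.default_rng(14)
        t = mask(random_blob(rng, (8, 8, 8), p_fg=0.2))
        brain = mask(np.ones((8, 8, 8)))
        r = evaluate_pair(t, t, brain)
        assert r.sensitivity == 1 and r.dice == pytest.approx(1)
        assert r.pcc == pytest.approx(1) and r.hd95_mm == 0

    def test_whole_brain_ctv_overtreats(self):
        rng = np.random.default_rng(15)
        brain = mask(np.ones((8, 8, 8)))
        t = mask(random_blob(rng, (8, 8, 8), p_fg=0.2))
        r = evaluate_pair(brain, t, brain)
        assert r.sensitivity == 1.0
        assert r.specificity == 0.0

    def test_counted_fixture_all_six_metrics(self):
        brain = np.ones((16, 16, 16), dtype=bool)
        truth = np.zeros((16, 16, 16)); truth[4:8, 4:8, 4:8] = 1   # 64
        pred = np.zeros((16, 16, 16)); pred[4:8, 4:8, 4:10] = 1    # 96
        tp, fp, fn = 64.0, 32.0, 0.0
        tn = 16**3 - tp - fp
        r = evaluate_pair(mask(pred), mask(truth), mask(brain))
        assert r.sensitivity == pytest.approx(tp / (tp + fn))
        assert r.specificity == pytest.approx(tn / (tn + fp))
        assert r.dice == pytest.approx(2 * tp / (2 * tp + fp + fn), rel=1e-6)
        assert r.tversky_002_098 == pytest.approx(
            tp / (tp + 0.02 * fp + 0.98 * fn), rel=1e-6)
        params_beta = 1 / (64 / 16**3 + 1)
        assert r.pcc == pytest.approx(
            tp / (tp + (1 - params_beta) * fp + params_beta * fn), rel=1e-6)
        assert r.hd95_mm == pytest.approx(
            brute_force_hd95(pred > 0, truth > 0, (3, 3, 3)), rel=1e-9)

    def test_empty_target_rejected(self):
        o = mask(np.ones((4, 4, 4)))
        with pytest.raises(ValueError):
            evaluate_pair(o, mask(np.zeros((4, 4, 4))), o)
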