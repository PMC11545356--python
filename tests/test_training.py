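"""Anchor assignment rules, loss identities (hand-evaluated cases), the
cross-view gradient-flow property and training-loop contracts."""

import dataclasses
import math

import numpy as np
import pytest

from scaphonet.config import scaled_run_config
from scaphonet.geometry import (
    AnchorGrid, AxisBox, OrientedBox, build_anchor_grid,
)
from scaphonet.nnkit import Tensor, sigmoid
from scaphonet.training import (
    AnchorTargets, IGNORE, NEGATIVE, POSITIVE, _BatchSampler,
    assign_anchor_targets, detection_cls_loss, fusion_cls_loss,
    regression_loss, squash_delta_angles, total_loss, train_stage2,
)


def single_anchor_grid(boxes):
    """Wrap explicit corner-form anchors in an AnchorGrid."""
    g = AnchorGrid((1,), (1.0,), (1.0,), (1.0,))
    g.per_level = [np.asarray(boxes, dtype=float)]
    return g


class TestAnchorAssignment:
    def test_gt_equal_to_anchor_positive_zero_delta(self):
        grid = single_anchor_grid([[0, 0, 10, 10], [40, 40, 50, 50]])
        gt = OrientedBox(5, 5, 10, 10, 0.0)
        t = assign_anchor_targets(grid, [gt], 0.5, 0.4)
        assert t.labels[0] == POSITIVE
        assert t.labels[1] == NEGATIVE
        assert np.allclose(t.deltas[0], 0, atol=1e-12)

    def test_empty_gt_all_negative(self):
        grid = single_anchor_grid([[0, 0, 10, 10], [5, 5, 15, 15]])
        t = assign_anchor_targets(grid, [], 0.5, 0.4)
        assert t.n_pos == 0
        assert np.all(t.labels == NEGATIVE)

    def test_threshold_rule_pos_ignore_neg(self):
        """Three anchors with analytically known IoUs 0.6 / ~0.45 / ~0.1
        against one axis-aligned gt, thresholds (0.5, 0.4)."""
        # axis overlap of equal 10x10 boxes shifted by s: (10-s)/(10+s)
        s_60 = 10 * (1 - 0.6) / (1 + 0.6)      # IoU 0.60
        s_45 = 10 * (1 - 0.45) / (1 + 0.45)    # IoU 0.45
        s_10 = 10 * (1 - 0.1) / (1 + 0.1)      # IoU 0.10
        grid = single_anchor_grid([
            [s_60, 0, 10 + s_60, 10],
            [s_45, 0, 10 + s_45, 10],
            [s_10, 0, 10 + s_10, 10],
        ])
        gt = OrientedBox(5, 5, 10, 10, 0.0)
        t = assign_anchor_targets(grid, [gt], 0.5, 0.4)
        assert list(t.labels) == [POSITIVE, IGNORE, NEGATIVE]

    def test_argmax_fallback_guarantees_a_positive(self):
        grid = single_anchor_grid([[0, 0, 4, 4], [20, 20, 24, 24]])
        gt = OrientedBox(30, 30, 3, 1, 0.7)  # overlaps nothing
        t = assign_anchor_targets(grid, [gt], 0.5, 0.4)
        assert t.n_pos == 1
        assert t.labels[1] == POSITIVE  # nearest center

    def test_bad_thresholds_rejected(self):
        grid = single_anchor_grid([[0, 0, 4, 4]])
        with pytest.raises(ValueError):
            assign_anchor_targets(grid, [], 0.4, 0.5)


def targets_with(labels, deltas=None):
    labels = np.asarray(labels, dtype=np.int8)
    if deltas is None:
        deltas = np.zeros((labels.size, 5))
    return AnchorTargets(labels, np.asarray(deltas, dtype=float))


class TestRegressionLoss:
    def test_perfect_prediction_zero(self):
        t = targets_with([1, 0], [[0.1, 0.2, 0.3, -0.1, 0.5], np.zeros(5)])
        pred = Tensor(np.array([[0.1, 0.2, 0.3, -0.1, 0.5], np.zeros(5)]))
        assert regression_loss(t, pred).item() == pytest.approx(0.0)

    def test_half_offset_quadratic_regime(self):
        """One positive, all five components off by 0.5 -> 5 * 0.5^2/2."""
        t = targets_with([1], [np.zeros(5)])
        pred = Tensor(np.full((1, 5), 0.5))
        assert regression_loss(t, pred).item() == pytest.approx(0.625)

    def test_two_offset_linear_regime(self):
        """One positive, components off by 2.0 -> 5 * (2 - 0.5)."""
        t = targets_with([1], [np.zeros(5)])
        pred = Tensor(np.full((1, 5), 2.0))
        assert regression_loss(t, pred).item() == pytest.approx(7.5)

    def test_no_positives_returns_zero(self):
        t = targets_with([0, 0])
        assert regression_loss(t, Tensor(np.ones((2, 5)))).item() == 0.0

    def test_zero_iff_exact_match(self, rng):
        d = rng.standard_normal((3, 5))
        t = targets_with([1, 1, 1], d)
        assert regression_loss(t, Tensor(d.copy())).item() == 0.0
        assert regression_loss(t, Tensor(d + 0.01)).item() > 0.0


class TestDetectionClsLoss:
    def test_hand_case_two_ln_two(self):
        """N=2, N_pos=1, y=(1,0), p=(0.5,0.5) -> 2 ln 2."""
        t = targets_with([1, 0])
        loss = detection_cls_loss(t, Tensor(np.array([0.5, 0.5])))
        assert loss.item() == pytest.approx(2 * math.log(2), abs=1e-6)

    def test_near_zero_for_confident_correct(self):
        t = targets_with([1, 0, 0])
        loss = detection_cls_loss(t, Tensor(np.array([1.0, 0.0, 0.0])))
        assert loss.item() < 1e-5

    def test_invariant_to_added_perfect_negatives(self):
        t1 = targets_with([1, 0])
        t2 = targets_with([1, 0, 0, 0, 0, 0])
        p1 = Tensor(np.array([0.7, 0.2]))
        p2 = Tensor(np.array([0.7, 0.2, 0.0, 0.0, 0.0, 0.0]))
        assert detection_cls_loss(t1, p1).item() == pytest.approx(
            detection_cls_loss(t2, p2).item(), abs=1e-5)

    def test_ignored_anchors_excluded(self):
        t1 = targets_with([1, -1])
        loss = detection_cls_loss(t1, Tensor(np.array([0.8, 0.01])))
        expect = -math.log(0.8)
        assert loss.item() == pytest.approx(expect, abs=1e-6)


class TestTotalLoss:
    def make_outputs(self, rng, m=6):
        return {
            "AP": {"scores": Tensor(rng.standard_normal((1, m, 1))),
                   "deltas": Tensor(rng.standard_normal((1, m, 5)))},
            "LA": {"scores": Tensor(rng.standard_normal((1, m, 1))),
                   "deltas": Tensor(rng.standard_normal((1, m, 5)))},
        }

    def test_total_is_exact_sum_of_components(self, rng):
        for _ in range(10):
            t_ap = targets_with(rng.integers(-1, 2, size=6))
            t_la = targets_with(rng.integers(-1, 2, size=6))
            probs = Tensor(np.array([[0.7, 0.3]]))
            lb = total_loss(t_ap, t_la, probs, self.make_outputs(rng), 1)
            parts = (lb.ap_cls.item() + lb.ap_reg.item() + lb.la_cls.item()
                     + lb.la_reg.item() + lb.fusion_cls.item())
            assert lb.total.item() == pytest.approx(parts, rel=1e-12)
            assert all(v >= 0 for k, v in lb.values().items())

    def test_fusion_half_half_gives_ln_two(self):
        probs = Tensor(np.array([[0.5, 0.5]]))
        assert fusion_cls_loss(probs, np.array([1])).item() == pytest.approx(
            math.log(2), abs=1e-6)

    def test_all_perfect_gives_zero_total(self):
        t = targets_with([1], [np.zeros(5)])
        outputs = {
            v: {"scores": Tensor(np.full((1, 1, 1), 30.0)),
                "deltas": Tensor(np.zeros((1, 1, 5)))}
            for v in ("AP", "LA")
        }
        probs = Tensor(np.array([[1.0 - 1e-9, 1e-9]]))
        lb = total_loss(t, t, probs, outputs, 1)
        assert lb.total.item() == pytest.approx(0.0, abs=1e-5)

    def test_squash_applies_tanh_to_angle_only(self, rng):
        raw = Tensor(rng.standard_normal((4, 5)))
        out = squash_delta_angles(raw)
        assert np.allclose(out.data[:, :4], raw.data[:, :4])
        assert np.allclose(out.data[:, 4], np.tanh(raw.data[:, 4]))


class TestGradientFlow:
    def test_fusion_loss_reaches_la_backbone(self):
        """Backpropagating only the fusion term must move LA-pathway
        weights (the cross-view information-transfer mechanism), verified
        against a finite-difference probe."""
        from scaphonet.backbone import BackboneConfig
        from scaphonet.fracture_net import (
            ContextExtractorConfig, HeadConfig, MultiViewFractureNet)
        from scaphonet.nnkit import softmax_cross_entropy
        rng = np.random.default_rng(3)
        net = MultiViewFractureNet(BackboneConfig.tiny(),
                                   ContextExtractorConfig(), HeadConfig(2, 1),
                                   16, rng)
        net.eval()  # frozen statistics make the finite difference clean
        ap = rng.random((1, 1, 32, 32)).astype(np.float64)
        la = rng.random((1, 1, 32, 32)).astype(np.float64)

        def loss_value():
            _, outputs = net.forward_pair(ap, la)
            return softmax_cross_entropy(outputs["fusion_logits"],
                                         np.array([0]))

        loss = loss_value()
        loss.backward()
        w = net.la_backbone.stem.layers[0].conv.weight
        assert w.grad is not None and np.abs(w.grad).max() > 0
        idx = np.unravel_index(np.abs(w.grad).argmax(), w.grad.shape)
        eps = 1e-4
        orig = w.data[idx]
        w.data[idx] = orig + eps
        lp = loss_value().item()
        w.data[idx] = orig - eps
        lm = loss_value().item()
        w.data[idx] = orig
        assert w.grad[idx] == pytest.approx((lp - lm) / (2 * eps), rel=0.05)


class TestTrainingLoop:
    def test_batch_sampler_never_repeats_within_batch(self):
        rng = np.random.default_rng(0)
        sampler = _BatchSampler(8, 12, rng)
        for _ in range(20):
            batch = sampler.next_batch()
            assert len(batch) == len(set(batch)) == 8

    def test_sampler_cycles_through_epochs(self):
        rng = np.random.default_rng(0)
        sampler = _BatchSampler(10, 5, rng)
        seen = []
        for _ in range(2):
            seen += sampler.next_batch()
        assert sorted(seen) == list(range(10))

    def test_same_seed_identical_loss_logs(self, small_crops):
        crops, _ = small_crops
        cfg = scaled_run_config().stage2
        cfg = dataclasses.replace(
            cfg, train=dataclasses.replace(cfg.train, iterations=3))
        _, _, log1 = train_stage2(crops[:4], cfg, seed=5)
        _, _, log2 = train_stage2(crops[:4], cfg, seed=5)
        assert log1 == log2

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError):
            train_stage2([], scaled_run_config().stage2, seed=0)
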