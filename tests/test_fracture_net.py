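"""Stage-2 network components: context extractor, weight transform, fusion,
classification head, detection heads, and the paired forward contract."""

import numpy as np
import pytest

from scaphonet.backbone import BackboneConfig
from scaphonet.fracture_net import (
    ClassificationHead, ContextExtractor, ContextExtractorConfig,
    DetectionHead, FusionModule, HeadConfig, MultiViewFractureNet,
    WeightTransform, flatten_head_map,
)
from scaphonet.nnkit import Tensor, no_grad


@pytest.fixture
def nprng():
    return np.random.default_rng(13)


class TestContextExtractor:
    def test_zero_input_zero_output(self, nprng):
        ce = ContextExtractor(8, ContextExtractorConfig(), nprng)
        ce.integrate.bias.data[:] = 0
        out = ce.forward(Tensor(np.zeros((1, 8, 6, 6), np.float32)))
        assert np.all(out.data == 0)

    @pytest.mark.parametrize("shape", [(1, 8, 5, 7), (2, 16, 6, 6),
                                       (1, 64, 4, 4)])
    def test_shape_preserved(self, nprng, shape):
        ce = ContextExtractor(shape[1], ContextExtractorConfig(), nprng)
        out = ce.forward(Tensor(np.zeros(shape, np.float32)))
        assert out.data.shape == shape

    def test_channels_not_divisible_rejected(self, nprng):
        with pytest.raises(ValueError):
            ContextExtractor(6, ContextExtractorConfig(), nprng)

    @pytest.mark.parametrize("mode", ["accumulate", "pre_dilation"])
    def test_receptive_field_grows_with_branch(self, nprng, mode):
        """Gradient-footprint probe: the dilated branch 4 output must see a
        wider input neighborhood than branch 1."""
        cfg = ContextExtractorConfig(mode=mode)
        ce = ContextExtractor(8, cfg, nprng)
        # eval mode: batch statistics would couple every pixel globally
        x = Tensor(nprng.random((1, 8, 41, 41)).astype(np.float32),
                   requires_grad=True)
        # prime running statistics, then freeze
        ce.forward(Tensor(nprng.random((2, 8, 41, 41)).astype(np.float32)))
        ce.eval()

        def footprint(branch_index):
            x.grad = None
            b = ce.branches[branch_index]
            t = b.spatial.forward(b.compress.forward(x))
            y = b.dilated.forward(t)
            # gradient of the center output pixel wrt the input
            g = np.zeros_like(y.data)
            g[0, :, 20, 20] = 1.0
            y.backward(g)
            nz = np.nonzero(np.abs(x.grad).sum(axis=(0, 1)))
            return max(nz[0].max() - nz[0].min(), nz[1].max() - nz[1].min())

        assert footprint(3) > footprint(0)


class TestWeightTransform:
    def test_zero_parameters_give_half(self, nprng):
        wt = WeightTransform(4, nprng)
        for lin in (wt.fc1, wt.fc2):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        w = wt.forward(Tensor(np.ones((1, 4))), Tensor(np.ones((1, 4))))
        assert np.allclose(w.data, 0.5)

    def test_outputs_strictly_in_unit_interval(self, nprng):
        wt = WeightTransform(8, nprng, dtype=np.float64)
        for _ in range(20):
            w = wt.forward(Tensor(nprng.standard_normal((2, 8))),
                           Tensor(nprng.standard_normal((2, 8))))
            assert np.all(w.data > 0) and np.all(w.data < 1)

    def test_hand_forward_oracle(self, nprng):
        """Length-2 input with hand-set affine weights, float64."""
        wt = WeightTransform(2, nprng, dtype=np.float64)
        wt.fc1.weight.data = np.array([[1.0, 0.0], [0.0, 1.0],
                                       [1.0, -1.0], [0.5, 0.5]])
        wt.fc1.bias.data = np.array([0.1, -0.2])
        wt.fc2.weight.data = np.array([[2.0, 0.0], [0.0, -1.0]])
        wt.fc2.bias.data = np.array([0.0, 0.3])
        ap = np.array([[0.5, -1.0]])
        la = np.array([[2.0, 0.25]])
        z = np.concatenate([ap, la], axis=1)
        h = z @ wt.fc1.weight.data + wt.fc1.bias.data
        h = np.where(h > 0, h, 0.01 * h)  # LeakyReLU
        expect = 1 / (1 + np.exp(-(h @ wt.fc2.weight.data + wt.fc2.bias.data)))
        got = wt.forward(Tensor(ap), Tensor(la))
        assert np.allclose(got.data, expect, atol=1e-6)

    def test_dimension_mismatch_rejected(self, nprng):
        wt = WeightTransform(4, nprng)
        with pytest.raises(ValueError):
            wt.forward(Tensor(np.ones((1, 4))), Tensor(np.ones((1, 3))))


class TestFusion:
    def test_forced_ones_is_concat(self, nprng):
        fm = FusionModule(3, 1, nprng)
        ap, la = Tensor(np.array([[1.0, 2, 3]])), Tensor(np.array([[4.0, 5, 6]]))
        fused = fm.forward([ap], [la], force_weights=1.0)
        assert np.allclose(fused.data, [[1, 2, 3, 4, 5, 6]])

    def test_forced_zeros_is_zero(self, nprng):
        fm = FusionModule(3, 2, nprng)
        vecs = [Tensor(nprng.standard_normal((1, 3))) for _ in range(2)]
        fused = fm.forward(vecs, vecs, force_weights=0.0)
        assert np.allclose(fused.data, 0)

    def test_two_level_hand_computed_sum(self, nprng):
        fm = FusionModule(2, 2, nprng, dtype=np.float64)
        for wt in fm.transforms:  # force W = sigmoid(0) = 0.5 per level
            for lin in (wt.fc1, wt.fc2):
                lin.weight.data[:] = 0
                lin.bias.data[:] = 0
        ap = [Tensor(np.array([[1.0, 2.0]])), Tensor(np.array([[3.0, 4.0]]))]
        la = [Tensor(np.array([[5.0, 6.0]])), Tensor(np.array([[7.0, 8.0]]))]
        fused = fm.forward(ap, la)
        # per level: concat(ap*0.5, la*0.5); fused = level sums
        expect = np.array([[0.5 + 1.5, 1.0 + 2.0, 2.5 + 3.5, 3.0 + 4.0]])
        assert np.allclose(fused.data, expect)

    def test_level_count_mismatch_rejected(self, nprng):
        fm = FusionModule(2, 2, nprng)
        v = [Tensor(np.ones((1, 2)))]
        with pytest.raises(ValueError):
            fm.forward(v, v)

    def test_zeroed_la_with_ones_weights_keeps_ap_half(self, nprng):
        """Single-view degenerate configuration of the same code path."""
        fm = FusionModule(3, 1, nprng)
        ap = Tensor(np.array([[1.0, -2.0, 3.0]]))
        la = Tensor(np.zeros((1, 3)))
        fused = fm.forward([ap], [la], force_weights=1.0)
        assert np.allclose(fused.data[0, :3], ap.data[0])
        assert np.allclose(fused.data[0, 3:], 0)


class TestClassificationHead:
    def test_probabilities_sum_to_one(self, nprng):
        head = ClassificationHead(8, nprng)
        p = head.forward(Tensor(nprng.standard_normal((3, 8))))
        assert np.allclose(p.data.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_half_half(self, nprng):
        head = ClassificationHead(8, nprng)
        for lin in (head.fc1, head.fc2):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        p = head.forward(Tensor(np.ones((1, 8))))
        assert np.allclose(p.data, 0.5)

    def test_hand_softmax_oracle(self, nprng):
        head = ClassificationHead(4, nprng, dtype=np.float64)
        head.fc1.weight.data = np.eye(4)[:, :2]
        head.fc1.bias.data = np.zeros(2)
        head.fc2.weight.data = np.array([[1.0, -1.0], [0.5, 0.5]])
        head.fc2.bias.data = np.array([0.2, -0.2])
        fused = np.array([[1.0, 2.0, -1.0, 0.5]])
        h = np.maximum(fused @ head.fc1.weight.data, 0)
        logits = h @ head.fc2.weight.data + head.fc2.bias.data
        e = np.exp(logits - logits.max())
        assert np.allclose(head.forward(Tensor(fused)).data, e / e.sum(),
                           atol=1e-9)


class TestDetectionHeads:
    def test_paper_channel_counts(self, nprng):
        head = DetectionHead(16, HeadConfig(25, 1), nprng)
        s, d = head.forward(Tensor(np.zeros((1, 16, 8, 8), np.float32)))
        assert s.data.shape[1] == 25
        assert d.data.shape[1] == 125
        assert s.data.shape[2:] == (8, 8) and d.data.shape[2:] == (8, 8)

    def test_flatten_is_bijective_in_anchor_order(self):
        """(level, y, x, anchor) indices round-trip through the flattening."""
        a, depth, h, w = 3, 5, 2, 4
        # encode the (y, x, anchor, component) index into the value
        vals = np.zeros((1, a * depth, h, w))
        for anchor in range(a):
            for comp in range(depth):
                for y in range(h):
                    for x in range(w):
                        vals[0, anchor * depth + comp, y, x] = (
                            ((y * w + x) * a + anchor) * depth + comp)
        flat = flatten_head_map(Tensor(vals), a, depth)
        expect = np.arange(h * w * a * depth).reshape(h * w * a, depth)
        assert np.array_equal(flat.data[0], expect)

    def test_bad_channel_factorization_rejected(self):
        with pytest.raises(ValueError):
            flatten_head_map(Tensor(np.zeros((1, 7, 2, 2))), 2, 5)


@pytest.fixture(scope="module")
def tiny_net():
    rng = np.random.default_rng(99)
    return MultiViewFractureNet(BackboneConfig.tiny(),
                                ContextExtractorConfig(), HeadConfig(2, 1),
                                16, rng)


class TestForwardPair:
    def test_eval_mode_deterministic(self, tiny_net):
        tiny_net.eval()
        rng = np.random.default_rng(0)
        ap = rng.random((1, 1, 64, 64)).astype(np.float32)
        la = rng.random((1, 1, 64, 64)).astype(np.float32)
        with no_grad():
            p1, o1 = tiny_net.forward_pair(ap, la)
            p2, o2 = tiny_net.forward_pair(ap, la)
        assert np.array_equal(p1.data, p2.data)
        assert np.array_equal(o1["AP"]["scores"].data, o2["AP"]["scores"].data)

    def test_view_permutation_changes_outputs(self, tiny_net):
        tiny_net.eval()
        rng = np.random.default_rng(1)
        ap = rng.random((1, 1, 64, 64)).astype(np.float32)
        la = rng.random((1, 1, 64, 64)).astype(np.float32)
        with no_grad():
            _, o1 = tiny_net.forward_pair(ap, la)
            _, o2 = tiny_net.forward_pair(la, ap)
        assert not np.allclose(o1["AP"]["scores"].data, o2["AP"]["scores"].data)

    def test_missing_view_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            tiny_net.forward_pair(None, np.zeros((1, 1, 64, 64), np.float32))

    def test_output_shapes_match_anchor_count(self, tiny_net):
        tiny_net.eval()
        with no_grad():
            p, o = tiny_net.forward_pair(
                np.zeros((1, 1, 64, 64), np.float32),
                np.zeros((1, 1, 64, 64), np.float32))
        m = (16 * 16 + 8 * 8 + 4 * 4) * 2
        assert o["AP"]["scores"].data.shape == (1, m, 1)
        assert o["LA"]["deltas"].data.shape == (1, m, 5)
        assert p.data.shape == (1, 2)
        assert np.allclose(p.data.sum(axis=1), 1, atol=1e-6)

    def test_golden_forward_regression(self, tiny_net):
        """Fixed-seed checkpoint forward must reproduce frozen values."""
        tiny_net.eval()
        ap = np.linspace(0, 1, 64 * 64, dtype=np.float32).reshape(1, 1, 64, 64)
        la = ap[:, :, ::-1].copy()
        with no_grad():
            p, o = tiny_net.forward_pair(ap, la)
        import json
        from pathlib import Path
        golden = json.loads(
            (Path(__file__).parent / "data" / "golden_forward.json").read_text())
        assert np.allclose(p.data, golden["probs"], atol=1e-5)
        assert np.allclose(o["AP"]["scores"].data[0, :5, 0],
                           golden["ap_scores_head"], atol=1e-5)
        assert np.allclose(o["LA"]["deltas"].data[0, 100],
                           golden["la_delta_100"], atol=1e-5)
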