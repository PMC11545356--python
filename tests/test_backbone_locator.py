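"""FPN merge semantics, RoI Align against the closed-form bilinear oracle,
region proposal decoding and the stage-1 not-found contract."""

import numpy as np
import pytest

from scaphonet import nnkit
from scaphonet.backbone import Backbone, BackboneConfig, FPN, PyramidFeatures
from scaphonet.imaging import ImageRecord, PreprocessConfig
from scaphonet.locator import (
    ScaphoidLocator, ScaphoidNotFoundError, Stage1Config, decode_axis_deltas,
    detect_scaphoid, encode_axis_deltas, propose_regions,
)
from scaphonet.nnkit import Tensor


@pytest.fixture
def nprng():
    return np.random.default_rng(11)


class TestBackbone:
    def test_three_stage_maps_with_doubling_strides(self, nprng):
        bb = Backbone(BackboneConfig.tiny(), nprng)
        outs = bb.forward(Tensor(np.zeros((1, 1, 64, 64), np.float32)))
        shapes = [o.data.shape for o in outs]
        assert shapes == [(1, 16, 16, 16), (1, 32, 8, 8), (1, 64, 4, 4)]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BackboneConfig("bad", (16, 32), (1, 1))


class TestFPN:
    def make_identity_fpn(self, channels, levels, nprng):
        """Lateral = identity 1x1, smoothing = identity 3x3 (center tap)."""
        fpn = FPN([channels] * levels, channels, nprng)
        for lat in fpn.laterals:
            lat.weight.data = np.eye(channels, dtype=np.float32).reshape(
                channels, channels, 1, 1)
            lat.bias.data[:] = 0
        for sm in fpn.smooths:
            sm.weight.data[:] = 0
            for c in range(channels):
                sm.weight.data[c, c, 1, 1] = 1.0
            sm.bias.data[:] = 0
        return fpn

    def test_additive_merge_oracle(self, nprng):
        """With identity projections, level i = lateral_i + 2x upsample of
        the merged deeper level (hand-computable on 4x4/2x2 maps)."""
        fpn = self.make_identity_fpn(2, 2, nprng)
        shallow = nprng.standard_normal((1, 2, 4, 4)).astype(np.float32)
        deep = nprng.standard_normal((1, 2, 2, 2)).astype(np.float32)
        out = fpn.forward([Tensor(shallow), Tensor(deep)])
        expect0 = shallow + deep.repeat(2, axis=2).repeat(2, axis=3)
        assert np.allclose(out[0].data, expect0, atol=1e-6)
        assert np.allclose(out[1].data, deep, atol=1e-6)

    def test_all_zero_inputs_zero_pyramid(self, nprng):
        fpn = FPN([4, 4], 4, nprng)
        for conv in fpn.laterals + fpn.smooths:
            conv.bias.data[:] = 0
        out = fpn.forward([Tensor(np.zeros((1, 4, 8, 8), np.float32)),
                           Tensor(np.zeros((1, 4, 4, 4), np.float32))])
        assert all(np.all(o.data == 0) for o in out)

    def test_single_level_projection_only(self, nprng):
        fpn = self.make_identity_fpn(3, 1, nprng)
        x = nprng.standard_normal((1, 3, 4, 4)).astype(np.float32)
        out = fpn.forward([Tensor(x)])
        assert np.allclose(out[0].data, x, atol=1e-6)

    def test_non_doubling_sizes_rejected(self, nprng):
        fpn = FPN([2, 2], 2, nprng)
        with pytest.raises(ValueError):
            fpn.forward([Tensor(np.zeros((1, 2, 6, 6), np.float32)),
                         Tensor(np.zeros((1, 2, 2, 2), np.float32))])

    def test_pyramid_features_invariants(self):
        with pytest.raises(ValueError):
            PyramidFeatures([Tensor(np.zeros((1, 2, 4, 4))),
                             Tensor(np.zeros((1, 3, 2, 2)))], (4, 8))
        with pytest.raises(ValueError):
            PyramidFeatures([Tensor(np.zeros((1, 2, 4, 4))),
                             Tensor(np.zeros((1, 2, 2, 2)))], (8, 8))


def bilinear(feature, x, y):
    """Closed-form bilinear interpolation at fractional (x, y)."""
    h, w = feature.shape
    x0 = min(max(int(np.floor(x)), 0), w - 2)
    y0 = min(max(int(np.floor(y)), 0), h - 2)
    fx, fy = x - x0, y - y0
    return ((1 - fy) * (1 - fx) * feature[y0, x0]
            + (1 - fy) * fx * feature[y0, x0 + 1]
            + fy * (1 - fx) * feature[y0 + 1, x0]
            + fy * fx * feature[y0 + 1, x0 + 1])


class TestRoiAlign:
    def test_constant_map_constant_pool(self):
        f = Tensor(np.full((1, 1, 5, 5), 3.25))
        out = nnkit.roi_align(f, np.array([[0.3, 0.7, 4.1, 3.9]]), 3)
        assert np.allclose(out.data, 3.25)

    def test_matches_bilinear_oracle_exhaustively(self, nprng):
        """All 1-sample-per-bin configurations on <=4x4 maps."""
        for h, w in [(2, 2), (3, 4), (4, 4)]:
            feat = nprng.standard_normal((h, w))
            t = Tensor(feat[None, None])
            for _ in range(20):
                x0, y0 = nprng.uniform(0, w - 1.2), nprng.uniform(0, h - 1.2)
                x1 = nprng.uniform(x0 + 0.5, w - 0.5)
                y1 = nprng.uniform(y0 + 0.5, h - 0.5)
                for o in (1, 2, 3):
                    out = nnkit.roi_align(t, np.array([[x0, y0, x1, y1]]), o)
                    bw, bh = (x1 - x0) / o, (y1 - y0) / o
                    for i in range(o):
                        for j in range(o):
                            sx = np.clip(x0 + (j + 0.5) * bw, 0, w - 1)
                            sy = np.clip(y0 + (i + 0.5) * bh, 0, h - 1)
                            assert out.data[0, 0, i, j] == pytest.approx(
                                bilinear(feat, sx, sy), rel=1e-9, abs=1e-12)

    def test_integer_aligned_box_returns_map_values(self):
        feat = np.arange(16.0).reshape(4, 4)
        # bin centers at integer coordinates 1 and 2
        out = nnkit.roi_align(Tensor(feat[None, None]),
                              np.array([[0.5, 0.5, 2.5, 2.5]]), 2)
        assert np.allclose(out.data[0, 0], [[5, 6], [9, 10]])

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            nnkit.roi_align(Tensor(np.zeros((1, 1, 4, 4))),
                            np.array([[2.0, 1.0, 2.0, 3.0]]), 2)


class TestProposals:
    def grid(self):
        from scaphonet.geometry import build_anchor_grid
        return build_anchor_grid((32, 32), (8,), (16,), (1.0,), (1.0,))

    def test_axis_delta_roundtrip(self, nprng):
        anchors = self.grid().centers_sizes
        boxes = anchors.copy()
        boxes[:, 0] += nprng.uniform(-4, 4, anchors.shape[0])
        boxes[:, 2] *= nprng.uniform(0.5, 2, anchors.shape[0])
        deltas = encode_axis_deltas(boxes, anchors)
        back = decode_axis_deltas(deltas, anchors)
        assert np.allclose(back[:, 2] - back[:, 0], boxes[:, 2], atol=1e-9)
        assert np.allclose((back[:, 0] + back[:, 2]) / 2, boxes[:, 0], atol=1e-9)

    def test_top_n_and_ordering(self, nprng):
        grid = self.grid()
        m = grid.boxes.shape[0]
        logits = nprng.standard_normal(m)
        props = propose_regions(logits, np.zeros((m, 4)), grid, top_n=5,
                                image_size=(32, 32))
        assert len(props) <= 5
        scores = [p.score for p in props]
        assert scores == sorted(scores, reverse=True)

    def test_single_proposal(self, nprng):
        grid = self.grid()
        m = grid.boxes.shape[0]
        props = propose_regions(nprng.standard_normal(m), np.zeros((m, 4)),
                                grid, top_n=1, image_size=(32, 32))
        assert len(props) == 1

    def test_hand_set_high_score_anchor_returned_first(self):
        grid = self.grid()
        m = grid.boxes.shape[0]
        logits = np.full(m, -6.0)
        logits[5] = 6.0  # an interior location: its anchor is not clipped
        props = propose_regions(logits, np.zeros((m, 4)), grid, top_n=3,
                                image_size=(32, 32))
        cs = grid.centers_sizes[5]
        assert props[0].box.cx == pytest.approx(cs[0])
        assert props[0].box.cy == pytest.approx(cs[1])


class TestDetectScaphoid:
    def test_blank_image_with_suppressed_model_not_found(self, nprng):
        cfg = Stage1Config(input_size=(64, 64), base_sizes=(16., 24., 32.))
        model = ScaphoidLocator(cfg, nprng)
        # force the RoI scoring head to emit strongly negative logits
        model.roi_score.weight.data[:] = 0
        model.roi_score.bias.data[:] = -20.0
        img = ImageRecord("blank", "AP", np.full((64, 64), 128, np.uint8), 8)
        with pytest.raises(ScaphoidNotFoundError):
            detect_scaphoid(img, model, PreprocessConfig())

    def test_detection_deterministic(self, nprng):
        cfg = Stage1Config(input_size=(64, 64), base_sizes=(16., 24., 32.))
        model = ScaphoidLocator(cfg, nprng)
        model.roi_score.bias.data[:] = 5.0  # guarantee a confident detection
        model.roi_delta.weight.data[:] = 0  # identity refinement
        model.roi_delta.bias.data[:] = 0
        img = ImageRecord("s", "AP",
                          (np.random.default_rng(0).random((80, 90)) * 255)
                          .astype(np.uint8), 8)
        d1 = detect_scaphoid(img, model, PreprocessConfig())
        d2 = detect_scaphoid(img, model, PreprocessConfig())
        assert d1.box == d2.box and d1.score == d2.score
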