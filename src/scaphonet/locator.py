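"""Stage-1 scaphoid localization: a two-stage region-proposal detector.

A residual backbone feeds an FPN; a region proposal network (RPN) scores
dense axis-aligned anchors and regresses box deltas; RoI Align pools each
proposal's features by bilinear interpolation (one sample per bin, no
coordinate rounding); a small fully connected head rescores and refines the
proposals.  Exactly one scaphoid exists per radiograph, so inference keeps
the single highest-scoring refined box, mapped back to original image
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnkit
from .backbone import Backbone, BackboneConfig, FPN
from .geometry import AnchorGrid, AxisBox, build_anchor_grid, nms_axis
from .imaging import ImageRecord, PreprocessConfig, apply_clahe, resize_image
from .nnkit import (
    Conv2d, ConvBNReLU, Linear, Module, Tensor, concat, no_grad, relu,
    reshape, roi_align, sigmoid, transpose,
)

__all__ = [
    "Stage1Config", "Detection", "ScaphoidNotFoundError", "ScaphoidLocator",
    "propose_regions", "decode_axis_deltas", "encode_axis_deltas",
    "detect_scaphoid",
]


class ScaphoidNotFoundError(RuntimeError):
    """No proposal cleared the score floor — the scaphoid was not located."""


@dataclass(frozen=True)
class Detection:
    """A scored box (axis-aligned for stage 1, oriented for stage 2)."""

    box: object  # AxisBox | OrientedBox
    score: float
    label: str = "scaphoid"

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("detection score must lie in [0, 1]")


@dataclass
class Stage1Config:
    """Stage-1 architecture, anchor and inference settings.

    The anchor menu (base sizes 32/64/128 over three levels, ratios
    0.5/1/2) targets a ~150x150 px scaphoid in a 1400x1200 frame; the
    score floor, proposal count and NMS threshold are package defaults
    (unvalidated against the original system, which does not state them).
    """

    input_size: tuple[int, int] = (1400, 1200)  # (width, height)
    backbone: BackboneConfig = field(default_factory=BackboneConfig.tiny)
    fpn_channels: int = 64
    level_strides: tuple[int, ...] = (4, 8, 16)
    base_sizes: tuple[float, ...] = (32.0, 64.0, 128.0)
    aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    scales: tuple[float, ...] = (1.0,)
    proposal_top_n: int = 20
    rpn_nms_iou: float = 0.5
    score_floor: float = 0.05
    roi_size: int = 7
    roi_hidden: int = 128

    def anchor_grid(self) -> AnchorGrid:
        return build_anchor_grid(self.input_size, self.level_strides,
                                 self.base_sizes, self.aspect_ratios, self.scales)


def encode_axis_deltas(boxes_cs: np.ndarray, anchors_cs: np.ndarray) -> np.ndarray:
    """Axis-aligned 4-delta encoding (center offsets + log scales)."""
    out = np.empty((boxes_cs.shape[0], 4))
    out[:, 0] = (boxes_cs[:, 0] - anchors_cs[:, 0]) / anchors_cs[:, 2]
    out[:, 1] = (boxes_cs[:, 1] - anchors_cs[:, 1]) / anchors_cs[:, 3]
    out[:, 2] = np.log(boxes_cs[:, 2] / anchors_cs[:, 2])
    out[:, 3] = np.log(boxes_cs[:, 3] / anchors_cs[:, 3])
    return out


def decode_axis_deltas(deltas: np.ndarray, anchors_cs: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_axis_deltas`; returns corner-form rows."""
    cx = anchors_cs[:, 0] + deltas[:, 0] * anchors_cs[:, 2]
    cy = anchors_cs[:, 1] + deltas[:, 1] * anchors_cs[:, 3]
    w = anchors_cs[:, 2] * np.exp(np.clip(deltas[:, 2], -8, 8))
    h = anchors_cs[:, 3] * np.exp(np.clip(deltas[:, 3], -8, 8))
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


class RPNHead(Module):
    """3x3 conv + ReLU stem with sibling 1x1 objectness / delta convolutions."""

    def __init__(self, channels: int, anchors_per_loc: int,
                 rng: np.random.Generator):
        super().__init__()
        self.a = anchors_per_loc
        self.stem = Conv2d(channels, channels, 3, rng)
        self.obj = Conv2d(channels, anchors_per_loc, 1, rng, padding=0)
        self.delta = Conv2d(channels, anchors_per_loc * 4, 1, rng, padding=0)

    def forward(self, level: Tensor) -> tuple[Tensor, Tensor]:
        x = relu(self.stem.forward(level))
        return self.obj.forward(x), self.delta.forward(x)


def _flatten_rpn(t: Tensor, a: int, depth: int) -> Tensor:
    n, c, h, w = t.data.shape
    t = reshape(t, (n, a, depth, h, w))
    t = transpose(t, (0, 3, 4, 1, 2))
    return reshape(t, (n, h * w * a, depth))


class ScaphoidLocator(Module):
    def __init__(self, config: Stage1Config, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.backbone = Backbone(config.backbone, rng)
        stage_ch = list(config.backbone.stage_channels[-3:])
        self.fpn = FPN(stage_ch, config.fpn_channels, rng)
        a = len(config.aspect_ratios) * len(config.scales)
        self.rpn = RPNHead(config.fpn_channels, a, rng)
        pooled = config.fpn_channels * config.roi_size**2
        self.roi_fc1 = Linear(pooled, config.roi_hidden, rng)
        self.roi_score = Linear(config.roi_hidden, 1, rng)
        self.roi_delta = Linear(config.roi_hidden, 4, rng)

    def rpn_forward(self, x: Tensor) -> tuple[list[Tensor], Tensor, Tensor]:
        """Backbone + FPN + RPN; outputs flattened in anchor order."""
        pyramid = self.fpn.forward(self.backbone.forward(x))
        objs, deltas = [], []
        for level in pyramid:
            o, d = self.rpn.forward(level)
            objs.append(_flatten_rpn(o, self.rpn.a, 1))
            deltas.append(_flatten_rpn(d, self.rpn.a, 4))
        return pyramid, concat(objs, axis=1), concat(deltas, axis=1)

    def roi_forward(self, finest: Tensor, boxes: np.ndarray,
                    stride: int) -> tuple[Tensor, Tensor]:
        """Score + refine proposals pooled from the finest pyramid level."""
        pooled = roi_align(finest, boxes, self.config.roi_size,
                           spatial_scale=1.0 / stride)
        flat = reshape(pooled, (boxes.shape[0], -1))
        hidden = relu(self.roi_fc1.forward(flat))
        return self.roi_score.forward(hidden), self.roi_delta.forward(hidden)


def propose_regions(obj_logits: np.ndarray, deltas: np.ndarray,
                    anchors: AnchorGrid, top_n: int,
                    nms_iou: float = 0.7,
                    image_size: tuple[int, int] | None = None
                    ) -> list[Detection]:
    """Decode RPN outputs into top-N scored axis-aligned proposals.

    Per-anchor objectness is squashed with a sigmoid; deltas decode against
    the anchor grid; boxes are clipped to the image; axis-aligned NMS then
    keeps the ``top_n`` highest scores, returned in descending order.
    """
    scores = 1.0 / (1.0 + np.exp(-np.clip(obj_logits.reshape(-1).astype(np.float64),
                                          -60, 60)))
    boxes = decode_axis_deltas(deltas.reshape(-1, 4), anchors.centers_sizes)
    if image_size is not None:
        w, h = image_size
        boxes[:, 0::2] = boxes[:, 0::2].clip(0, w - 1)
        boxes[:, 1::2] = boxes[:, 1::2].clip(0, h - 1)
    valid = (boxes[:, 2] - boxes[:, 0] > 1) & (boxes[:, 3] - boxes[:, 1] > 1)
    idx = np.flatnonzero(valid)
    # pre-NMS shortlist keeps NMS cheap on dense grids
    if idx.size > 4 * top_n:
        idx = idx[np.argsort(-scores[idx], kind="stable")[: 4 * top_n]]
    kept = nms_axis(boxes[idx], scores[idx], nms_iou)
    kept = [int(idx[k]) for k in kept][:top_n]
    return [Detection(AxisBox(*boxes[k]), float(scores[k])) for k in kept]


def preprocess_stage1(img: ImageRecord, config: Stage1Config,
                      preprocess: PreprocessConfig) -> tuple[np.ndarray, float, float]:
    """CLAHE + resize to the stage-1 input size; returns the image tensor
    (1, 1, H, W) in [0, 1] plus the per-axis scale factors applied."""
    enhanced = apply_clahe(img, preprocess.clahe_clip, preprocess.clahe_tiles)
    resized, _, _ = resize_image(enhanced, config.input_size)
    sx = config.input_size[0] / img.width
    sy = config.input_size[1] / img.height
    x = (resized.pixels.astype(np.float32) / resized.max_value)[None, None]
    return x, sx, sy


def detect_scaphoid(img: ImageRecord, model: ScaphoidLocator,
                    preprocess: PreprocessConfig) -> Detection:
    """Locate the single scaphoid region in a whole-wrist radiograph.

    Returns the highest-scoring second-stage box mapped back to original
    image coordinates.  Raises :class:`ScaphoidNotFoundError` when no
    proposal clears the score floor.
    """
    config = model.config
    x, sx, sy = preprocess_stage1(img, config, preprocess)
    model.eval()
    with no_grad():
        pyramid, obj, deltas = model.rpn_forward(Tensor(x))
        anchors = config.anchor_grid()
        proposals = propose_regions(obj.data[0], deltas.data[0], anchors,
                                    config.proposal_top_n,
                                    image_size=config.input_size)
        if not proposals:
            raise ScaphoidNotFoundError(f"{img.subject_id}/{img.view}: no proposals")
        boxes = np.array([[p.box.x_min, p.box.y_min, p.box.x_max, p.box.y_max]
                          for p in proposals])
        score_logit, refine = model.roi_forward(pyramid[0], boxes,
                                                config.level_strides[0])
    scores = 1.0 / (1.0 + np.exp(-np.clip(
        score_logit.data.reshape(-1).astype(np.float64), -60, 60)))
    cs = np.stack([(boxes[:, 0] + boxes[:, 2]) / 2, (boxes[:, 1] + boxes[:, 3]) / 2,
                   boxes[:, 2] - boxes[:, 0], boxes[:, 3] - boxes[:, 1]], axis=1)
    refined = decode_axis_deltas(refine.data, cs)
    w, h = config.input_size
    refined[:, 0::2] = refined[:, 0::2].clip(0, w - 1)
    refined[:, 1::2] = refined[:, 1::2].clip(0, h - 1)
    valid = (refined[:, 2] - refined[:, 0] > 1) & (refined[:, 3] - refined[:, 1] > 1)
    keep = nms_axis(refined, scores, config.rpn_nms_iou)
    keep = [k for k in keep if scores[k] >= config.score_floor and valid[k]]
    if not keep:
        raise ScaphoidNotFoundError(
            f"{img.subject_id}/{img.view}: no box above score floor "
            f"{config.score_floor}")
    best = keep[0]
    box = AxisBox(refined[best, 0] / sx, refined[best, 1] / sy,
                  refined[best, 2] / sx, refined[best, 3] / sy)
    return Detection(box, float(scores[best]))
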