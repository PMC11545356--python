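"""Decode stage-2 head outputs, rotated NMS, and classification rescoring.

Rescoring adds the fusion classification score — zeroed when it falls below
a threshold (default 0.5) — to each retained detection's score, so that
cross-view classification evidence re-ranks the per-view boxes:
``rescore = threshold(cls, 0.5) + det`` with range exactly [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AnchorGrid, OrientedBox, decode_deltas, nms_rotated
from .imaging import ViewPairRecord
from .locator import Detection
from .nnkit import no_grad
from .training import prepare_crop_pixels

__all__ = [
    "RescoredDetection", "PairPrediction", "decode_detections", "rescore",
    "predict_pair",
]


@dataclass(frozen=True)
class RescoredDetection:
    """A detection plus the fusion classification evidence behind it."""

    box: OrientedBox
    det_score: float
    cls_score: float
    rescore: float

    def __post_init__(self):
        if not 0.0 <= self.rescore <= 2.0:
            raise ValueError("rescore must lie in [0, 2]")


@dataclass
class PairPrediction:
    subject_id: str
    fracture_probability: float
    is_fracture: bool
    detections: dict[str, list[RescoredDetection]] = field(default_factory=dict)


def decode_detections(score_logits: np.ndarray, raw_deltas: np.ndarray,
                      anchors: AnchorGrid, score_floor: float = 0.05,
                      nms_iou: float = 0.2, top_k: int = 3,
                      pre_nms_top_n: int = 200) -> list[Detection]:
    """Raw per-anchor head outputs -> scored oriented detections.

    Scores pass a sigmoid; the raw angle is squashed with tanh before the
    delta decode; candidates below ``score_floor`` are discarded; greedy
    rotated NMS keeps the ``top_k`` survivors in score order.
    """
    scores = 1.0 / (1.0 + np.exp(-np.asarray(score_logits, dtype=np.float64)
                                 .reshape(-1)))
    deltas = np.asarray(raw_deltas, dtype=np.float64).reshape(-1, 5).copy()
    deltas[:, 2:4] = deltas[:, 2:4].clip(-8, 8)
    deltas[:, 4] = np.tanh(deltas[:, 4])
    keep = np.flatnonzero(scores >= score_floor)
    if keep.size == 0:
        return []
    if keep.size > pre_nms_top_n:
        keep = keep[np.argsort(-scores[keep], kind="stable")[:pre_nms_top_n]]
    rows = decode_deltas(deltas[keep], anchors.centers_sizes[keep])
    boxes = [OrientedBox(*row) for row in rows]
    kept = nms_rotated(boxes, scores[keep], nms_iou)[:top_k]
    return [Detection(boxes[i], float(scores[keep[i]]), label="fracture")
            for i in kept]


def rescore(dets: list[Detection], cls_score: float,
            cls_threshold: float = 0.5) -> list[RescoredDetection]:
    """Add the (thresholded) fusion classification score to every detection
    score and re-sort by the combined value, descending."""
    if not 0.0 <= cls_score <= 1.0:
        raise ValueError("cls_score must lie in [0, 1]")
    gate = cls_score if cls_score >= cls_threshold else 0.0
    out = [RescoredDetection(d.box, d.score, cls_score, gate + d.score)
           for d in dets]
    out.sort(key=lambda r: -r.rescore)
    return out


def predict_pair(pair: ViewPairRecord, model, anchors: AnchorGrid,
                 infer_config, clahe_clip: float = 2.0,
                 clahe_tiles: tuple[int, int] = (8, 8),
                 zero_la: bool = False) -> PairPrediction:
    """Full stage-2 inference for one crop pair.

    Runs the multi-view forward pass, decodes per-view oriented detections,
    rescored with the shared fusion classification score; the pair is called
    a fracture when the fusion probability reaches the decision threshold
    (>= convention).  ``zero_la`` blanks the lateral input — the single-view
    ablation hook.
    """
    if pair.ap is None or pair.la is None:
        raise ValueError(f"{pair.subject_id}: multi-view model requires both views")
    ap, la = prepare_crop_pixels(pair, clahe_clip, clahe_tiles)
    if zero_la:
        la = np.zeros_like(la)
    model.eval()
    with no_grad():
        probs, outputs = model.forward_pair(ap[None], la[None])
    cls_score = float(probs.data[0, 0])  # column 0 = fracture
    dets = {}
    for view in ("AP", "LA"):
        raw = decode_detections(outputs[view]["scores"].data[0],
                                outputs[view]["deltas"].data[0], anchors,
                                infer_config.score_floor, infer_config.nms_iou,
                                infer_config.top_k)
        dets[view] = rescore(raw, cls_score, infer_config.cls_threshold)
    return PairPrediction(pair.subject_id, cls_score,
                          cls_score >= infer_config.decision_threshold, dets)
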