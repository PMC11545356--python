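"""End-to-end pipeline: stage-1 localization -> crops -> stage-2 prediction.

``run_pipeline`` locates the scaphoid in both views (or takes the oracle
ground-truth boxes), cuts the square crops, runs the multi-view fracture
network and tallies classification and detection metrics.  Detection
overlap is evaluated in full-frame coordinates by mapping retained
detections back through the crop transform, so oracle and detector crops
are directly comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import line as draw_line

from .evaluation import ConfusionCounts, classification_metrics, detection_metrics
from .geometry import AxisBox, OrientedBox
from .imaging import ImageRecord, ViewPairRecord
from .inference import predict_pair
from .locator import ScaphoidNotFoundError, detect_scaphoid
from .phantom import CropTransform
from .imaging import resize_image

__all__ = ["CropPair", "run_pipeline", "write_overlay"]

log = logging.getLogger(__name__)


@dataclass
class CropPair:
    """A bare AP/LA crop pair for inference (no label bookkeeping)."""

    subject_id: str
    ap: ImageRecord
    la: ImageRecord


def _crop_from_box(img: ImageRecord, box: AxisBox, margin: float,
                   crop_size: int) -> tuple[ImageRecord, CropTransform]:
    side = int(round(max(max(box.w, box.h) * (1.0 + 2.0 * margin), 8)))
    x0 = int(round(box.cx - side / 2))
    y0 = int(round(box.cy - side / 2))
    x0 = min(max(x0, 0), max(img.width - side, 0))
    y0 = min(max(y0, 0), max(img.height - side, 0))
    x1 = min(x0 + side, img.width)
    y1 = min(y0 + side, img.height)
    crop = ImageRecord(img.subject_id, img.view, img.pixels[y0:y1, x0:x1],
                       img.bit_depth)
    resized, _, _ = resize_image(crop, (crop_size, crop_size))
    return resized, CropTransform(float(x0), float(y0),
                                  crop_size / crop.width, crop_size / crop.height)


def run_pipeline(records: list[ViewPairRecord], run_config, stage2_model,
                 anchors, stage1_model=None, oracle_stage1: bool = False,
                 out_dir: str | Path | None = None) -> dict:
    """Run the full system over whole-frame pairs and report metrics.

    With ``oracle_stage1`` the ground-truth scaphoid boxes replace stage-1
    detections (a pipeline-equivalence hook).  Subjects whose scaphoid
    cannot be located in either view are skipped and counted.
    """
    if not oracle_stage1 and stage1_model is None:
        raise ValueError("either a stage-1 model or oracle_stage1 is required")
    s2 = run_config.stage2
    counts = ConfusionCounts()
    det_preds = {"AP": {}, "LA": {}}
    det_truths = {"AP": {}, "LA": {}}
    subjects = []
    skipped = 0
    for rec in records:
        crops, tfs = {}, {}
        try:
            for view, img, gt_box in (("AP", rec.ap, rec.ap_scaphoid_box),
                                      ("LA", rec.la, rec.la_scaphoid_box)):
                if oracle_stage1:
                    if gt_box is None:
                        raise ScaphoidNotFoundError(f"{rec.subject_id}: no oracle box")
                    box = gt_box
                else:
                    box = detect_scaphoid(img, stage1_model,
                                          run_config.preprocess).box
                crops[view], tfs[view] = _crop_from_box(img, box, s2.crop_margin,
                                                        s2.crop_size)
        except ScaphoidNotFoundError as exc:
            log.warning("stage-1 miss, skipping subject: %s", exc)
            skipped += 1
            continue
        pair = CropPair(rec.subject_id, crops["AP"], crops["LA"])
        if out_dir is not None:
            crop_dir = Path(out_dir) / "crops"
            crop_dir.mkdir(parents=True, exist_ok=True)
            for view in ("AP", "LA"):
                iio.imwrite(crop_dir / f"{rec.subject_id}_{view}.png",
                            crops[view].pixels)
        pred = predict_pair(pair, stage2_model, anchors, s2.infer,
                            clahe_clip=s2.clahe_clip, clahe_tiles=s2.clahe_tiles)
        actual = rec.label == "fracture"
        if pred.is_fracture and actual:
            counts.tp += 1
        elif pred.is_fracture:
            counts.fp += 1
        elif actual:
            counts.fn += 1
        else:
            counts.tn += 1
        for view, gt in (("AP", rec.ap_fracture_boxes),
                         ("LA", rec.la_fracture_boxes)):
            retained = [d for d in pred.detections[view]
                        if d.rescore >= s2.infer.retain_rescore]
            # evaluate in full-frame coordinates
            unmapped = [
                type(d)(tfs[view].unmap_box(d.box), d.det_score, d.cls_score,
                        d.rescore) for d in retained
            ]
            det_preds[view][rec.subject_id] = unmapped
            det_truths[view][rec.subject_id] = list(gt)
        subjects.append({
            "subject_id": rec.subject_id,
            "label": rec.label,
            "fracture_probability": pred.fracture_probability,
            "is_fracture": pred.is_fracture,
            "detections": {
                v: [{"box": d.box.to_json(), "det_score": d.det_score,
                     "cls_score": d.cls_score, "rescore": d.rescore}
                    for d in det_preds[v][rec.subject_id]]
                for v in ("AP", "LA")
            },
        })
    report = {
        "n_subjects": len(records),
        "n_skipped": skipped,
        "stage1": "oracle" if oracle_stage1 else "detector",
        "classification": classification_metrics(counts) if counts.total else None,
        "detection": {
            v: detection_metrics(det_preds[v], det_truths[v], s2.infer.match_iou)
            for v in ("AP", "LA")
        } if det_truths["AP"] else None,
        "subjects": subjects,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "pipeline_results.json").write_text(json.dumps(report, indent=1))
        # full-frame overlays: ground truth red, retained predictions green
        by_id = {r.subject_id: r for r in records}
        for sid, rec in by_id.items():
            if sid not in det_preds["AP"]:
                continue
            for view, img, gt in (("AP", rec.ap, rec.ap_fracture_boxes),
                                  ("LA", rec.la, rec.la_fracture_boxes)):
                write_overlay(img, gt, [d.box for d in det_preds[view][sid]],
                              out_dir / "overlays" / f"{sid}_{view}.png")
    return report


def _draw_box(rgb: np.ndarray, corners: np.ndarray, color: tuple[int, int, int]) -> None:
    h, w = rgb.shape[:2]
    pts = np.rint(corners).astype(int)
    for i in range(4):
        r0, c0 = pts[i][1], pts[i][0]
        r1, c1 = pts[(i + 1) % 4][1], pts[(i + 1) % 4][0]
        rr, cc = draw_line(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rgb[rr[keep], cc[keep]] = color


def write_overlay(img: ImageRecord, truth_boxes: list[OrientedBox],
                  predicted_boxes: list[OrientedBox], path: str | Path) -> None:
    """Write a PNG with ground truth drawn in red and predictions in green."""
    gray = (img.pixels.astype(np.float64) / img.max_value * 255).astype(np.uint8)
    rgb = np.stack([gray, gray, gray], axis=-1)
    for b in truth_boxes:
        _draw_box(rgb, b.corners(), (255, 0, 0))
    for b in predicted_boxes:
        _draw_box(rgb, b.corners(), (0, 255, 0))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, rgb)
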