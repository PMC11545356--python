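"""Confusion-matrix metrics, detection evaluation and the stratified
five-fold cross-validation harness.

Classification metrics follow the standard confusion-matrix definitions
(accuracy = (TP+TN)/total, recall = sensitivity = TP/(TP+FN), precision =
TP/(TP+FP), specificity = TN/(TN+FP)); ratios with a zero denominator are
reported as flagged nulls, never silently as 0.

Detection evaluation is subject-level: a fracture subject counts as a true
positive when at least one retained detection overlaps a ground-truth box at
the match IoU; a normal subject counts as a false positive when any
detection is retained.  The mean IoU averages, over fracture subjects, the
best retained detection's overlap (0 when none was retained).  The retention
rule (rescore >= 1, i.e. the classification gate passed) and the match IoU
are configuration values logged in every report.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .geometry import OrientedBox, rotated_iou
from .imaging import ViewPairRecord
from .inference import PairPrediction, RescoredDetection, predict_pair

__all__ = [
    "ConfusionCounts", "FoldSplit", "EvalReport", "classification_metrics",
    "detection_metrics", "make_folds", "run_crossval", "evaluate_stage2",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy/recall/precision/sensitivity/specificity from TP/FP/TN/FN.

    Undefined ratios (zero denominator) are returned as None and named in
    the ``flags`` list.
    """
    if counts.total == 0:
        raise ValueError("empty confusion matrix")
    metrics = {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "recall": _ratio(counts.tp, counts.tp + counts.fn),
        "precision": _ratio(counts.tp, counts.tp + counts.fp),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp),
    }
    metrics["sensitivity"] = metrics["recall"]
    metrics["flags"] = sorted(k for k, v in metrics.items()
                              if v is None and k != "flags")
    return metrics


def detection_metrics(predictions: dict[str, list[RescoredDetection]],
                      truths: dict[str, list[OrientedBox]],
                      match_iou: float = 0.2) -> dict:
    """Subject-level detection evaluation for one view.

    ``predictions`` holds the *retained* detections per subject;
    ``truths`` the ground-truth fracture boxes (empty list = normal
    subject).  Subject id sets must match.
    """
    if set(predictions) != set(truths):
        raise ValueError("prediction/truth subject ids do not align")
    counts = ConfusionCounts()
    ious = []
    for sid, gt in truths.items():
        dets = predictions[sid]
        if gt:
            best = 0.0
            for det in dets:
                for g in gt:
                    best = max(best, rotated_iou(det.box, g))
            ious.append(best)
            if dets and best >= match_iou:
                counts.tp += 1
            else:
                counts.fn += 1
        else:
            if dets:
                counts.fp += 1
            else:
                counts.tn += 1
    cls = classification_metrics(counts)
    return {
        "mean_iou": float(np.mean(ious)) if ious else None,
        "accuracy": cls["accuracy"],
        "recall": cls["recall"],
        "precision": cls["precision"],
        "specificity": cls["specificity"],
        "match_iou": match_iou,
        "counts": {"tp": counts.tp, "fp": counts.fp,
                   "tn": counts.tn, "fn": counts.fn},
        "flags": cls["flags"],
    }


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def make_folds(records: list[ViewPairRecord], k: int = 5,
               seed: int = 0) -> list[FoldSplit]:
    """Stratified K-fold split over subjects, deterministic per seed.

    Test sets partition the cohort; per-class fold sizes differ by at most
    one (exact when the class size divides k).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = [r.label for r in records]
    for cls in set(labels):
        if labels.count(cls) < k:
            raise ValueError(f"class {cls!r} smaller than k={k}")
    ids = np.array([r.subject_id for r in records])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fid, (train_idx, test_idx) in enumerate(skf.split(ids, labels)):
        folds.append(FoldSplit(fid, tuple(ids[train_idx]), tuple(ids[test_idx])))
    return folds


def evaluate_stage2(model, crop_records: list[ViewPairRecord], anchors,
                    infer_config, clahe_clip: float = 2.0,
                    clahe_tiles: tuple[int, int] = (8, 8),
                    zero_la: bool = False
                    ) -> tuple[ConfusionCounts, dict, list[PairPrediction]]:
    """Run inference over crop pairs and tally classification + detection.

    Detections kept for detection metrics are those passing the retention
    rule ``rescore >= retain_rescore`` (classification gate open and the
    detector contributing).
    """
    counts = ConfusionCounts()
    det_preds = {"AP": {}, "LA": {}}
    det_truths = {"AP": {}, "LA": {}}
    predictions = []
    for rec in crop_records:
        pred = predict_pair(rec, model, anchors, infer_config,
                            clahe_clip=clahe_clip, clahe_tiles=clahe_tiles,
                            zero_la=zero_la)
        predictions.append(pred)
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
            det_truths[view][rec.subject_id] = list(gt)
            det_preds[view][rec.subject_id] = [
                d for d in pred.detections[view]
                if d.rescore >= infer_config.retain_rescore
            ]
    det = {view: detection_metrics(det_preds[view], det_truths[view],
                                   infer_config.match_iou)
           for view in ("AP", "LA")}
    return counts, det, predictions


@dataclass
class EvalReport:
    """Per-fold classification/detection metrics plus arithmetic averages."""

    folds: list[dict] = field(default_factory=list)
    average: dict = field(default_factory=dict)
    retention_rule: str = "rescore >= 1.0"

    def compute_average(self) -> None:
        def avg(path: list[str]) -> float | None:
            vals = []
            for fold in self.folds:
                v = fold
                for p in path:
                    v = v[p]
                if v is None:
                    return None
                vals.append(v)
            return float(np.mean(vals)) if vals else None

        self.average = {"classification": {}, "detection": {}}
        for m in ("accuracy", "recall", "precision", "sensitivity",
                  "specificity"):
            self.average["classification"][m] = avg(["classification", m])
        for view in ("AP", "LA"):
            self.average["detection"][view] = {
                m: avg(["detection", view, m])
                for m in ("mean_iou", "accuracy", "recall", "precision")
            }

    def to_json(self) -> dict:
        return {"folds": self.folds, "average": self.average,
                "retention_rule": self.retention_rule}

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(self.to_json(), indent=1))
        with open(out_dir / "report.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fold", "cls_accuracy", "cls_recall",
                             "cls_precision", "cls_specificity",
                             "ap_mean_iou", "ap_recall", "la_mean_iou",
                             "la_recall"])
            rows = [(str(f["fold_id"]), f) for f in self.folds]
            rows.append(("average", {"classification":
                                     self.average["classification"],
                                     "detection": self.average["detection"]}))
            for name, f in rows:
                writer.writerow([
                    name,
                    f["classification"]["accuracy"],
                    f["classification"]["recall"],
                    f["classification"]["precision"],
                    f["classification"]["specificity"],
                    f["detection"]["AP"]["mean_iou"],
                    f["detection"]["AP"]["recall"],
                    f["detection"]["LA"]["mean_iou"],
                    f["detection"]["LA"]["recall"],
                ])


def run_crossval(records: list[ViewPairRecord], config, seed: int,
                 k: int = 5, out_dir: str | Path | None = None) -> EvalReport:
    """Stratified K-fold cross-validation of stage 2 on full-frame records.

    Each fold crops the scaphoid regions (ground-truth boxes), trains the
    multi-view network on the training partition and evaluates on the held-
    out partition.  Reproducible from ``seed``.
    """
    from .phantom import make_crop_dataset
    from .training import train_stage2

    folds = make_folds(records, k=k, seed=seed)
    crops, _ = make_crop_dataset(records, config.crop_margin, config.crop_size)
    by_id = {r.subject_id: r for r in crops}
    report = EvalReport()
    for fold in folds:
        train_recs = [by_id[i] for i in fold.train_ids if i in by_id]
        test_recs = [by_id[i] for i in fold.test_ids if i in by_id]
        model, anchors, _ = train_stage2(train_recs, config,
                                         seed=seed * 1000 + fold.fold_id)
        counts, det, _ = evaluate_stage2(model, test_recs, anchors,
                                         config.infer, config.clahe_clip,
                                         config.clahe_tiles)
        report.folds.append({
            "fold_id": fold.fold_id,
            "n_train": len(train_recs),
            "n_test": len(test_recs),
            "classification": classification_metrics(counts),
            "detection": det,
        })
    report.compute_average()
    report.retention_rule = f"rescore >= {config.infer.retain_rescore}"
    if out_dir is not None:
        report.write(out_dir)
    return report
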