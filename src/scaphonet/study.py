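"""The package's desk-scale synthetic study, runnable end to end.

One seeded call generates a training cohort (120 AP/LA pairs) and a held-out
test cohort (40 pairs) from the phantom generator, trains the stage-2
multi-view network and the stage-1 scaphoid locator, evaluates
classification and oriented-box detection on the held-out pairs, trains the
zeroed-lateral single-view ablation (the degenerate configuration of the
same code path, for the recall comparison), and runs the full pipeline both
with oracle scaphoid boxes and with the trained stage-1 detector to measure
their metric difference.

All problem sizes here are the package's scaled-down study conditions (see
``docs/methods.md``); the clinical-scale defaults live in
:mod:`scaphonet.config`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np

from .config import RunConfig, scaled_run_config
from .evaluation import classification_metrics, evaluate_stage2
from .geometry import axis_iou_matrix
from .imaging import ImageRecord, ViewPairRecord
from .locator import ScaphoidNotFoundError, detect_scaphoid
from .phantom import PhantomConfig, generate_cohort, make_crop_dataset
from .pipeline import run_pipeline
from .training import train_stage1, train_stage2

__all__ = ["StudyResult", "run_scaled_study", "TRAIN_COHORT", "TEST_COHORT"]

# cohort composition mirrors one fold of the emulated five-fold protocol,
# scaled to 120 training / 40 held-out pairs at the cohort's 75:100 class mix
TRAIN_COHORT = {"n_fracture": 52, "n_normal": 68}
TEST_COHORT = {"n_fracture": 18, "n_normal": 22}


@dataclass
class StudyResult:
    config: RunConfig
    classification: dict
    detection: dict  # per view
    single_view_classification: dict
    single_view_detection: dict
    stage1_locate_rate: float  # fraction of views with IoU >= 0.5
    stage1_mean_iou: float
    pipeline_oracle: dict
    pipeline_detector: dict
    train_loss_first: float
    train_loss_last: float
    predictions: list


def _zero_la(records: list[ViewPairRecord]) -> list[ViewPairRecord]:
    """Blank the lateral view and drop its box supervision.

    The single-view baseline must not train the LA detection head against
    boxes that are invisible in a blank image; a record keeps its label
    through the AP boxes alone.
    """
    out = []
    for rec in records:
        blank = ImageRecord(rec.subject_id, "LA",
                            np.zeros_like(rec.la.pixels), rec.la.bit_depth)
        keep = rec if rec.ap_fracture_boxes or rec.label == "normal" else None
        if keep is None:
            # fracture visible only laterally: count it as AP-occult by
            # keeping the label via the LA boxes (cannot be stripped)
            out.append(replace(rec, la=blank))
        else:
            out.append(replace(rec, la=blank, la_fracture_boxes=[]))
    return out


def run_scaled_study(seed: int = 0, with_single_view: bool = True,
                     with_stage1: bool = True) -> StudyResult:
    """Run the full scaled study; deterministic per ``seed``."""
    ss = np.random.SeedSequence([int(seed), 7])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    cfg = scaled_run_config(seed)
    s2 = cfg.stage2
    train_recs, _ = generate_cohort(
        PhantomConfig(seed=seeds[0], **TRAIN_COHORT))
    test_recs, _ = generate_cohort(
        PhantomConfig(seed=seeds[1], **TEST_COHORT))
    train_crops, _ = make_crop_dataset(train_recs, s2.crop_margin, s2.crop_size)
    test_crops, _ = make_crop_dataset(test_recs, s2.crop_margin, s2.crop_size)

    model, anchors, loss_log = train_stage2(train_crops, s2, seed=seeds[2])
    counts, det, preds = evaluate_stage2(model, test_crops, anchors, s2.infer,
                                         s2.clahe_clip, s2.clahe_tiles)
    cls_metrics = classification_metrics(counts)

    single_metrics = {}
    single_det = {}
    if with_single_view:
        # the single-view baseline: the same architecture and seed with the
        # lateral input blanked throughout training and evaluation
        sv_model, sv_anchors, _ = train_stage2(_zero_la(train_crops), s2,
                                               seed=seeds[2])
        sv_counts, single_det, _ = evaluate_stage2(
            sv_model, test_crops, sv_anchors, s2.infer, s2.clahe_clip,
            s2.clahe_tiles, zero_la=True)
        single_metrics = classification_metrics(sv_counts)

    locate_rate = mean_iou1 = 0.0
    pipe_oracle = pipe_detector = None
    if with_stage1:
        stage1_model, _ = train_stage1(train_recs, cfg.stage1,
                                       cfg.stage1_train, cfg.preprocess,
                                       seed=seeds[3])
        ious = []
        for rec in test_recs:
            for img, gt in ((rec.ap, rec.ap_scaphoid_box),
                            (rec.la, rec.la_scaphoid_box)):
                try:
                    box = detect_scaphoid(img, stage1_model, cfg.preprocess).box
                except ScaphoidNotFoundError:
                    ious.append(0.0)
                    continue
                ious.append(float(axis_iou_matrix(
                    np.array([[box.x_min, box.y_min, box.x_max, box.y_max]]),
                    np.array([[gt.x_min, gt.y_min, gt.x_max, gt.y_max]]))[0, 0]))
        locate_rate = float(np.mean([i >= 0.5 for i in ious]))
        mean_iou1 = float(np.mean(ious))
        pipe_oracle = run_pipeline(test_recs, cfg, model, anchors,
                                   oracle_stage1=True)
        pipe_detector = run_pipeline(test_recs, cfg, model, anchors,
                                     stage1_model=stage1_model)
    return StudyResult(
        config=cfg,
        classification=cls_metrics,
        detection=det,
        single_view_classification=single_metrics,
        single_view_detection=single_det,
        stage1_locate_rate=locate_rate,
        stage1_mean_iou=mean_iou1,
        pipeline_oracle=pipe_oracle,
        pipeline_detector=pipe_detector,
        train_loss_first=loss_log[0]["total"],
        train_loss_last=loss_log[-1]["total"],
        predictions=preds,
    )
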