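"""Anchor target assignment, loss functions and the seeded training loops.

Loss conventions: regression is smooth-L1 over the 5 delta components of the
positive anchors, normalized by the positive count; the detection score loss
is binary cross-entropy summed over all non-ignored anchors but normalized
by the positive count (not the total), which keeps the contribution of the
vast negative majority from swamping the positives; the fusion classifier
uses 2-class cross-entropy.  The total stage-2 loss is the plain sum of the
five components (AP cls + AP reg + LA cls + LA reg + fusion cls).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fracture_net import MultiViewFractureNet, build_fracture_net
from .geometry import (
    AnchorGrid, AxisBox, OrientedBox, axis_iou_matrix, encode_boxes,
    normalize_angle, rotated_iou,
)
from .imaging import ViewPairRecord, apply_clahe
from .locator import (
    ScaphoidLocator, Stage1Config, encode_axis_deltas, propose_regions,
)
from .nnkit import (
    SGD, Adam, Tensor, clip as tclip, clip_grad_norm, log as tlog, reshape,
    sigmoid, smooth_l1, softmax_cross_entropy, take_rows, tanh, concat,
)

__all__ = [
    "AnchorTargets", "LossBreakdown", "assign_anchor_targets",
    "regression_loss", "detection_cls_loss", "fusion_cls_loss", "total_loss",
    "squash_delta_angles", "train_stage2", "train_stage1",
    "save_checkpoint", "load_stage2_checkpoint", "load_stage1_checkpoint",
    "prepare_crop_pixels",
]

POSITIVE, NEGATIVE, IGNORE = 1, 0, -1


@dataclass
class AnchorTargets:
    """Per-anchor assignment: label in {positive, negative, ignore} plus the
    encoded regression target for every positive anchor."""

    labels: np.ndarray  # (M,) int8: 1 positive, 0 negative, -1 ignore
    deltas: np.ndarray  # (M, 5); rows valid only where labels == 1

    @property
    def n_pos(self) -> int:
        return int((self.labels == POSITIVE).sum())

    @property
    def n(self) -> int:
        return int((self.labels != IGNORE).sum())


@dataclass
class LossBreakdown:
    """The five stage-2 loss components; total is their exact sum."""

    ap_cls: Tensor
    ap_reg: Tensor
    la_cls: Tensor
    la_reg: Tensor
    fusion_cls: Tensor

    @property
    def total(self) -> Tensor:
        return (self.ap_cls + self.ap_reg + self.la_cls + self.la_reg
                + self.fusion_cls)

    def values(self) -> dict[str, float]:
        return {
            "ap_cls": self.ap_cls.item(), "ap_reg": self.ap_reg.item(),
            "la_cls": self.la_cls.item(), "la_reg": self.la_reg.item(),
            "fusion_cls": self.fusion_cls.item(), "total": self.total.item(),
        }


def assign_anchor_targets(anchors: AnchorGrid, gt_boxes: list[OrientedBox],
                          pos_iou: float = 0.5, neg_iou: float = 0.4
                          ) -> AnchorTargets:
    """Match axis-aligned anchors (as angle-0 oriented boxes) to ground truth.

    An anchor is positive when its rotated IoU with some ground-truth box
    reaches ``pos_iou`` or when it is that box's best-overlapping anchor
    (argmax fallback, nearest center on an all-zero tie); negative when its
    best IoU is below ``neg_iou``; ignored otherwise.  Positive anchors carry
    the encoded delta to their matched box.  With no ground truth (a normal
    image) every anchor is negative.
    """
    if pos_iou <= neg_iou:
        raise ValueError("pos_iou must exceed neg_iou")
    boxes = anchors.boxes
    cs = anchors.centers_sizes
    m = boxes.shape[0]
    labels = np.zeros(m, dtype=np.int8)
    deltas = np.zeros((m, 5))
    if not gt_boxes:
        return AnchorTargets(labels, deltas)
    best_iou = np.zeros(m)
    best_gt = np.full(m, -1)
    for gi, gt in enumerate(gt_boxes):
        corners = gt.corners()
        aabb = np.array([[corners[:, 0].min(), corners[:, 1].min(),
                          corners[:, 0].max(), corners[:, 1].max()]])
        cand = np.flatnonzero(axis_iou_matrix(boxes, aabb)[:, 0] > 0)
        ious = np.zeros(m)
        for ai in cand:
            ious[ai] = rotated_iou(AxisBox(*boxes[ai]).as_oriented(), gt)
        upd = ious > best_iou
        best_iou[upd] = ious[upd]
        best_gt[upd] = gi
        # argmax fallback: the best anchor for this gt is always positive
        if ious.max() > 0:
            ai = int(ious.argmax())
        else:
            d2 = (cs[:, 0] - gt.cx) ** 2 + (cs[:, 1] - gt.cy) ** 2
            ai = int(d2.argmin())
        best_iou[ai] = max(best_iou[ai], pos_iou)
        best_gt[ai] = gi
    labels[best_iou < neg_iou] = NEGATIVE
    labels[(best_iou >= neg_iou) & (best_iou < pos_iou)] = IGNORE
    pos = best_iou >= pos_iou
    labels[pos] = POSITIVE
    pos_idx = np.flatnonzero(pos)
    gt_rows = np.array([
        [g.cx, g.cy, g.w, g.h, g.theta]
        for g in (normalize_angle(b) for b in gt_boxes)
    ])
    deltas[pos_idx] = encode_boxes(gt_rows[best_gt[pos_idx]], cs[pos_idx])
    return AnchorTargets(labels, deltas)


def squash_delta_angles(raw_deltas: Tensor) -> Tensor:
    """Apply tanh to the angle component (column 4) of raw head deltas so the
    predicted 5-vector is comparable with the encoded target."""
    mask = np.zeros(raw_deltas.data.shape, dtype=raw_deltas.data.dtype)
    mask[..., 4] = 1.0
    return raw_deltas * (1.0 - mask) + tanh(raw_deltas) * mask


def regression_loss(targets: AnchorTargets, pred_deltas: Tensor,
                    beta: float = 1.0) -> Tensor:
    """Smooth-L1 over positive anchors' 5 components, divided by N_pos.

    ``pred_deltas`` is (M, 5) with the angle already squashed.  Returns an
    exact 0 tensor when there are no positives.
    """
    pos_idx = np.flatnonzero(targets.labels == POSITIVE)
    if pos_idx.size == 0:
        return Tensor(np.zeros((), dtype=pred_deltas.data.dtype))
    pred = take_rows(pred_deltas, pos_idx)
    diff = pred - Tensor(targets.deltas[pos_idx].astype(pred_deltas.data.dtype))
    return smooth_l1(diff, beta=beta).sum() * (1.0 / pos_idx.size)


def detection_cls_loss(targets: AnchorTargets, pred_probs: Tensor,
                       eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy over all non-ignored anchors / max(N_pos, 1).

    Normalizing by the positive count instead of the anchor total keeps the
    loss invariant to adding perfectly classified negatives.
    """
    keep = np.flatnonzero(targets.labels != IGNORE)
    if keep.size == 0:
        return Tensor(np.zeros((), dtype=pred_probs.data.dtype))
    y = (targets.labels[keep] == POSITIVE).astype(pred_probs.data.dtype)
    p = tclip(take_rows(reshape(pred_probs, (-1,)), keep), eps, 1.0 - eps)
    bce = -(Tensor(y) * tlog(p) + Tensor(1.0 - y) * tlog(1.0 - p))
    return bce.sum() * (1.0 / max(targets.n_pos, 1))


def fusion_cls_loss(probs: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """2-class cross-entropy on fusion softmax output.

    ``probs`` is (N, 2) with column 0 the fracture probability; ``labels``
    holds 1 for fracture, 0 for normal.
    """
    n = probs.data.shape[0]
    picked = take_rows(reshape(probs, (-1,)),
                       np.arange(n) * 2 + (1 - np.asarray(labels)))
    return -tlog(tclip(picked, eps, 1.0)).sum() * (1.0 / n)


def total_loss(ap_targets: AnchorTargets, la_targets: AnchorTargets,
               fusion_probs: Tensor, view_outputs: dict,
               pair_label: int, beta: float = 1.0,
               fusion_logits: Tensor | None = None) -> LossBreakdown:
    """Assemble the five-component stage-2 loss for a single pair (N=1).

    When ``fusion_logits`` is supplied the fusion term uses the numerically
    stable fused log-softmax cross-entropy (identical value, non-vanishing
    gradient when the softmax saturates); otherwise it is computed from the
    probabilities directly.
    """
    ap_scores = sigmoid(reshape(view_outputs["AP"]["scores"], (-1,)))
    la_scores = sigmoid(reshape(view_outputs["LA"]["scores"], (-1,)))
    ap_deltas = squash_delta_angles(reshape(view_outputs["AP"]["deltas"], (-1, 5)))
    la_deltas = squash_delta_angles(reshape(view_outputs["LA"]["deltas"], (-1, 5)))
    if fusion_logits is not None:
        # column 0 is the fracture class
        fusion = softmax_cross_entropy(fusion_logits,
                                       np.array([1 - pair_label]))
    else:
        fusion = fusion_cls_loss(fusion_probs, np.array([pair_label]))
    return LossBreakdown(
        ap_cls=detection_cls_loss(ap_targets, ap_scores),
        ap_reg=regression_loss(ap_targets, ap_deltas, beta),
        la_cls=detection_cls_loss(la_targets, la_scores),
        la_reg=regression_loss(la_targets, la_deltas, beta),
        fusion_cls=fusion,
    )


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_crop_pixels(rec: ViewPairRecord, clahe_clip: float = 2.0,
                        clahe_tiles: tuple[int, int] = (8, 8)
                        ) -> tuple[np.ndarray, np.ndarray]:
    """CLAHE-enhance both crop views and scale to [0, 1] float32 planes."""
    out = []
    for img in (rec.ap, rec.la):
        enhanced = apply_clahe(img, clahe_clip, clahe_tiles)
        out.append((enhanced.pixels.astype(np.float32) / img.max_value)[None])
    return out[0], out[1]


class _BatchSampler:
    """Reshuffles the index permutation each epoch; batches never repeat a
    pair (batch size is capped at the dataset size)."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n = n
        self.batch = min(batch_size, n)
        self.rng = rng
        self._pool: list[int] = []

    def next_batch(self) -> list[int]:
        out: list[int] = []
        while len(out) < self.batch:
            if not self._pool:
                self._pool = list(self.rng.permutation(self.n))
            take = self._pool.pop()
            if take in out:  # epoch boundary inside a batch
                continue
            out.append(int(take))
        return out


def _hflip_crop(pixels: np.ndarray, boxes: list[OrientedBox]
                ) -> tuple[np.ndarray, list[OrientedBox]]:
    w = pixels.shape[-1]
    flipped = [normalize_angle(OrientedBox(w - 1 - b.cx, b.cy, b.w, b.h, -b.theta))
               for b in boxes]
    return pixels[..., ::-1].copy(), flipped


def _jitter(pixels: np.ndarray, factor: float) -> np.ndarray:
    mean = pixels.mean()
    return np.clip((pixels - mean) * factor + mean, 0.0, 1.0).astype(pixels.dtype)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model, path: str | Path, config_obj: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(config_obj).encode(), dtype=np.uint8).copy()
    np.savez(path, **state)


def _load_state(path: str | Path) -> tuple[dict, dict]:
    with np.load(Path(path)) as data:
        state = {k: data[k] for k in data.files}
    config_obj = json.loads(bytes(state.pop("__config__")).decode())
    return state, config_obj


def load_stage2_checkpoint(path: str | Path) -> tuple[MultiViewFractureNet, dict]:
    state, config_obj = _load_state(path)
    model = build_fracture_net(config_obj["model"], np.random.default_rng(0))
    model.load_state_dict(state)
    model.eval()
    return model, config_obj


def load_stage1_checkpoint(path: str | Path) -> tuple[ScaphoidLocator, dict]:
    from .config import stage1_config_from_json  # local import avoids a cycle
    state, config_obj = _load_state(path)
    model = ScaphoidLocator(stage1_config_from_json(config_obj["stage1"]),
                            np.random.default_rng(0))
    model.load_state_dict(state)
    model.eval()
    return model, config_obj


# ---------------------------------------------------------------------------
# stage-2 training loop
# ---------------------------------------------------------------------------

def train_stage2(crop_records: list[ViewPairRecord], config, seed: int,
                 out_dir: str | Path | None = None,
                 log_every: int = 10):
    """Train the multi-view fracture network on crop pairs.

    ``config`` is a :class:`scaphonet.config.Stage2Config`.  The loop is
    fully seeded: data order, augmentation draws and weight initialization
    all derive from ``seed``.  Returns ``(model, anchors, loss_log)`` where
    ``loss_log`` is a list of per-iteration component dicts; when ``out_dir``
    is given a ``stage2.npz`` checkpoint and ``stage2_loss.csv`` are written.
    """
    if not crop_records:
        raise ValueError("empty training manifest")
    ss = np.random.SeedSequence([seed, 2])
    init_rng, order_rng, aug_rng = (np.random.default_rng(s)
                                    for s in ss.spawn(3))
    model = MultiViewFractureNet(config.backbone, config.context,
                                 config.head_config(), config.fpn_channels,
                                 init_rng)
    anchors = config.anchor_grid()
    tc = config.train
    opt = (Adam(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
           if tc.optimizer == "adam"
           else SGD(model.parameters(), lr=tc.lr, momentum=0.9,
                    weight_decay=tc.weight_decay))
    # preprocess once; augmentation works on the cached planes
    planes = [prepare_crop_pixels(r, config.clahe_clip, config.clahe_tiles)
              for r in crop_records]
    boxes = [(list(r.ap_fracture_boxes), list(r.la_fracture_boxes))
             for r in crop_records]
    labels = [1 if r.label == "fracture" else 0 for r in crop_records]
    # targets for the un-augmented geometry are reusable
    base_targets = [
        (assign_anchor_targets(anchors, b_ap, tc.pos_iou, tc.neg_iou),
         assign_anchor_targets(anchors, b_la, tc.pos_iou, tc.neg_iou))
        for b_ap, b_la in boxes
    ]
    flip_targets: dict[int, tuple[AnchorTargets, AnchorTargets]] = {}
    sampler = _BatchSampler(len(crop_records), tc.batch_size, order_rng)
    model.train()
    loss_log: list[dict] = []
    for it in range(tc.iterations):
        idxs = sampler.next_batch()
        batch_ap, batch_la, batch_targets, batch_labels = [], [], [], []
        for i in idxs:
            ap, la = planes[i]
            b_ap, b_la = boxes[i]
            tgt = base_targets[i]
            if tc.augment:
                if aug_rng.random() < tc.hflip_probability:
                    if i not in flip_targets:
                        _, fb_ap = _hflip_crop(ap, b_ap)
                        _, fb_la = _hflip_crop(la, b_la)
                        flip_targets[i] = (
                            assign_anchor_targets(anchors, fb_ap, tc.pos_iou,
                                                  tc.neg_iou),
                            assign_anchor_targets(anchors, fb_la, tc.pos_iou,
                                                  tc.neg_iou))
                    ap = ap[..., ::-1]
                    la = la[..., ::-1]
                    tgt = flip_targets[i]
                lo, hi = tc.contrast_jitter
                ap = _jitter(ap, aug_rng.uniform(lo, hi))
                la = _jitter(la, aug_rng.uniform(lo, hi))
            batch_ap.append(ap)
            batch_la.append(la)
            batch_targets.append(tgt)
            batch_labels.append(labels[i])
        probs, outputs = model.forward_pair(np.stack(batch_ap),
                                            np.stack(batch_la))
        comps = {"ap_cls": 0.0, "ap_reg": 0.0, "la_cls": 0.0, "la_reg": 0.0,
                 "fusion_cls": 0.0}
        per_sample = []
        for b, (t_ap, t_la) in enumerate(batch_targets):
            row = take_rows(probs, np.array([b]))
            view_b = {v: {k: take_rows(outputs[v][k], np.array([b]))
                          for k in ("scores", "deltas")} for v in ("AP", "LA")}
            logits_b = take_rows(outputs["fusion_logits"], np.array([b]))
            lb = total_loss(t_ap, t_la, row, view_b, batch_labels[b],
                            fusion_logits=logits_b)
            per_sample.append(lb)
        n = len(per_sample)
        batch_total = per_sample[0].total
        for lb in per_sample[1:]:
            batch_total = batch_total + lb.total
        batch_total = batch_total * (1.0 / n)
        for lb in per_sample:
            for k in comps:
                comps[k] += getattr(lb, k).item() / n
        opt.zero_grad()
        batch_total.backward()
        clip_grad_norm(opt.params, tc.grad_clip)
        opt.step()
        comps["total"] = sum(comps.values())
        comps["iteration"] = it
        loss_log.append(comps)
    model.eval()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / "stage2.npz",
                        {"model": model.config_json(),
                         "anchors": config.anchor_json(),
                         "crop_size": config.crop_size})
        with open(out_dir / "stage2_loss.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(loss_log[0]))
            writer.writeheader()
            writer.writerows(loss_log)
    return model, anchors, loss_log


# ---------------------------------------------------------------------------
# stage-1 training loop
# ---------------------------------------------------------------------------

def _rpn_targets(anchors_boxes: np.ndarray, anchors_cs: np.ndarray,
                 gt: AxisBox, pos_iou: float, neg_iou: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    gt_row = np.array([[gt.x_min, gt.y_min, gt.x_max, gt.y_max]])
    iou = axis_iou_matrix(anchors_boxes, gt_row)[:, 0]
    labels = np.full(iou.shape, IGNORE, dtype=np.int8)
    labels[iou < neg_iou] = NEGATIVE
    labels[iou >= pos_iou] = POSITIVE
    labels[int(iou.argmax())] = POSITIVE
    gt_cs = np.array([[gt.cx, gt.cy, gt.w, gt.h]])
    pos_idx = np.flatnonzero(labels == POSITIVE)
    deltas = np.zeros((anchors_cs.shape[0], 4))
    deltas[pos_idx] = encode_axis_deltas(np.repeat(gt_cs, pos_idx.size, axis=0),
                                         anchors_cs[pos_idx])
    return labels, deltas


def train_stage1(records: list[ViewPairRecord], stage1_config: Stage1Config,
                 train_config, preprocess, seed: int,
                 out_dir: str | Path | None = None):
    """Train the scaphoid locator on whole-frame pairs (both views used as
    independent images, batch size 1 as in the reference protocol)."""
    from .locator import preprocess_stage1  # local import for clarity
    if not records:
        raise ValueError("empty training manifest")
    ss = np.random.SeedSequence([seed, 1])
    init_rng, order_rng, aug_rng = (np.random.default_rng(s) for s in ss.spawn(3))
    model = ScaphoidLocator(stage1_config, init_rng)
    opt = SGD(model.parameters(), lr=train_config.lr,
              momentum=train_config.momentum,
              weight_decay=train_config.weight_decay)
    anchors = stage1_config.anchor_grid()
    aboxes, acs = anchors.boxes, anchors.centers_sizes
    # flatten to per-view samples with cached preprocessed planes
    samples = []
    for rec in records:
        for img, sb in ((rec.ap, rec.ap_scaphoid_box), (rec.la, rec.la_scaphoid_box)):
            if sb is None:
                continue
            x, sx, sy = preprocess_stage1(img, stage1_config, preprocess)
            gt = AxisBox(sb.x_min * sx, sb.y_min * sy, sb.x_max * sx, sb.y_max * sy)
            samples.append((x, gt))
    sampler = _BatchSampler(len(samples), 1, order_rng)
    w_img, h_img = stage1_config.input_size
    model.train()
    loss_log = []
    for it in range(train_config.iterations):
        x, gt = samples[sampler.next_batch()[0]]
        if aug_rng.random() < preprocess.hflip_probability:
            x = x[..., ::-1].copy()
            gt = AxisBox(w_img - 1 - gt.x_max, gt.y_min,
                         w_img - 1 - gt.x_min, gt.y_max)
        lo, hi = preprocess.contrast_jitter_range
        x = _jitter(x, aug_rng.uniform(lo, hi))
        pyramid, obj, deltas = model.rpn_forward(Tensor(x))
        labels, tdeltas = _rpn_targets(aboxes, acs, gt, train_config.pos_iou,
                                       train_config.neg_iou)
        rpn_tgt = AnchorTargets(labels, np.concatenate(
            [tdeltas, np.zeros((tdeltas.shape[0], 1))], axis=1))
        obj_p = sigmoid(reshape(obj, (-1,)))
        rpn_cls = detection_cls_loss(rpn_tgt, obj_p)
        pos_idx = np.flatnonzero(labels == POSITIVE)
        pred_d = take_rows(reshape(deltas, (-1, 4)), pos_idx)
        diff = pred_d - Tensor(tdeltas[pos_idx].astype(np.float32))
        rpn_reg = smooth_l1(diff).sum() * (1.0 / max(pos_idx.size, 1))
        # second stage: proposals + jittered/true gt boxes
        props = propose_regions(obj.data[0], deltas.data[0], anchors,
                                top_n=8, image_size=stage1_config.input_size)
        roi_boxes = [np.array([gt.x_min, gt.y_min, gt.x_max, gt.y_max])]
        for _ in range(3):
            jit = aug_rng.uniform(-0.15, 0.15, size=4) * np.array(
                [gt.w, gt.h, gt.w, gt.h])
            box = np.array([gt.x_min, gt.y_min, gt.x_max, gt.y_max]) + jit
            box[0::2] = box[0::2].clip(0, w_img - 2)
            box[1::2] = box[1::2].clip(0, h_img - 2)
            if box[2] - box[0] > 2 and box[3] - box[1] > 2:
                roi_boxes.append(box)
        for p in props:
            b = p.box
            if b.w > 2 and b.h > 2:
                roi_boxes.append(np.array([b.x_min, b.y_min, b.x_max, b.y_max]))
        roi_boxes = np.stack(roi_boxes)
        iou = axis_iou_matrix(roi_boxes, np.array(
            [[gt.x_min, gt.y_min, gt.x_max, gt.y_max]]))[:, 0]
        roi_labels = np.where(iou >= train_config.pos_iou, POSITIVE, NEGATIVE
                              ).astype(np.int8)
        roi_cs = np.stack([(roi_boxes[:, 0] + roi_boxes[:, 2]) / 2,
                           (roi_boxes[:, 1] + roi_boxes[:, 3]) / 2,
                           roi_boxes[:, 2] - roi_boxes[:, 0],
                           roi_boxes[:, 3] - roi_boxes[:, 1]], axis=1)
        gt_cs = np.array([[gt.cx, gt.cy, gt.w, gt.h]])
        score_logit, refine = model.roi_forward(pyramid[0], roi_boxes,
                                                stage1_config.level_strides[0])
        roi_tgt = AnchorTargets(roi_labels, np.zeros((roi_labels.size, 5)))
        roi_cls = detection_cls_loss(roi_tgt, sigmoid(reshape(score_logit, (-1,))))
        pos_r = np.flatnonzero(roi_labels == POSITIVE)
        if pos_r.size:
            tdel = encode_axis_deltas(np.repeat(gt_cs, pos_r.size, axis=0),
                                      roi_cs[pos_r])
            rdiff = take_rows(refine, pos_r) - Tensor(tdel.astype(np.float32))
            roi_reg = smooth_l1(rdiff).sum() * (1.0 / pos_r.size)
        else:
            roi_reg = Tensor(np.zeros((), dtype=np.float32))
        loss = rpn_cls + rpn_reg + roi_cls + roi_reg
        opt.zero_grad()
        loss.backward()
        clip_grad_norm(opt.params, train_config.grad_clip)
        opt.step()
        loss_log.append({"iteration": it, "rpn_cls": rpn_cls.item(),
                         "rpn_reg": rpn_reg.item(), "roi_cls": roi_cls.item(),
                         "roi_reg": roi_reg.item(), "total": loss.item()})
    model.eval()
    if out_dir is not None:
        from .config import stage1_config_to_json
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out_dir / "stage1.npz",
                        {"stage1": stage1_config_to_json(stage1_config)})
        with open(out_dir / "stage1_loss.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(loss_log[0]))
            writer.writeheader()
            writer.writerows(loss_log)
    return model, loss_log
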