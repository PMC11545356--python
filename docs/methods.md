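# Methods

## Problem and model

Scaphoid fractures — especially occult and non-displaced ones — are hard to
read on plain wrist radiographs.  This package implements a two-stage
system that mirrors the clinical reading workflow over paired
anterior-posterior (AP) and lateral (LA) projections:

1. **Stage 1 — scaphoid localization.** A two-stage region-proposal
   detector (residual backbone → feature pyramid network → region proposal
   network → RoI-Align + fully connected scoring/refinement head) finds the
   single scaphoid region in each whole-wrist frame.  Exactly one scaphoid
   exists per frame, so inference keeps the top-scoring refined box.

2. **Stage 2 — fracture classification and oriented detection.** Square
   scaphoid crops from both views pass through per-view pathways
   (backbone → four-branch dilated-convolution context extractor → FPN).
   Globally averaged pyramid features of corresponding levels feed a
   *multi-view fusion module*: per level *i*,

       W_i = sigmoid(FC2(LeakyReLU(FC1(concat(GAP(AP_i), GAP(LA_i))))))

   gates both views' channels, the gated vectors are concatenated and the
   per-level vectors summed; a two-layer classifier with softmax yields the
   fracture probability.  Per-view convolutional heads predict, per anchor,
   a fracture score and an oriented-box regression
   (tx, ty, tw, th, tθ).

### Oriented boxes and angle coding

Fracture lines are elongated and directional, so ground truth and
predictions are rotated rectangles (cx, cy, w, h, θ).  Angles use the
long-edge convention with θ normalized to (−π/4, π/4] (side lengths swap as
needed).  The regression code is anchor-relative: center offsets divided by
anchor size, log size ratios, and the linear angle code tθ = 4θ/π, so both
the target and the tanh-squashed network output live in [−1, 1].  Decoding
is the exact inverse; anchors are axis-aligned (the encoding has no anchor
angle term).

### Rescoring

The fusion classifier sees both views and is empirically the strongest
branch, so its probability re-ranks the per-view detections:

    rescore = (cls if cls ≥ 0.5 else 0) + det   ∈ [0, 2]

Detections are *retained* for reporting when rescore ≥ 1.0, i.e. the
classification gate is open and the detector contributes.  The retention
cut, the NMS threshold (0.2), the per-view top-k (3) and the score floor
(0.05) are package defaults: the source protocol does not state them.

### Losses

Per view: smooth-L1 (β = 1) over the five delta components of positive
anchors, normalized by the positive count N_pos; binary cross-entropy over
all non-ignored anchors, also normalized by N_pos (this keeps the dominant
negative class from swamping the loss and makes it invariant to adding
perfectly classified negatives).  The fusion classifier uses 2-class
cross-entropy (computed in the fused log-softmax form, which is numerically
stable when the softmax saturates).  The total is the plain sum
L = L_APcls + L_APreg + L_LAcls + L_LAreg + L_multiview_cls.  Training
backpropagates the sum, so the LA pathway receives gradient through the
fusion term even when its own detection loss is flat — the cross-view
information-transfer mechanism.

Anchor matching: an anchor is positive when its rotated IoU with a ground
truth box reaches `pos_iou`, or when it is that box's best-overlapping
anchor (with a nearest-center fallback when all overlaps are zero);
negative below `neg_iou`; ignored in between.  Clinical-scale defaults are
0.5/0.4.  The desk-scale configuration uses 0.25/0.15: thin bars a few
pixels wide at 45° cannot exceed rotated IoU ≈ 0.3 against any axis-aligned
anchor, and with 0.5/0.4 nearly every fracture would be matched by the
single fallback anchor only, starving the regression branch of signal.

## Synthetic phantom cohort

The clinical images are not public, so a phantom generator provides the
study data: per subject, a low-frequency bone texture, a bright elliptical
"scaphoid" blob, neighboring distractor blobs (the LA view gets an extra
occluding blob), and — for fracture subjects — a dark thin rotated bar
whose minimum-area rectangle is the ground-truth box.  One latent fracture
event drives both views: the same relative position within the blob (±10%
jitter) and orientation (±10° jitter), with independent per-view contrast.
An *occult* fraction (default 0.15, the midpoint of the cited 7–21%
clinical prevalence) renders the bar at near-noise contrast in one randomly
chosen view — the case multi-view fusion is designed to rescue.  The
default cohort is 100 normal + 75 fracture pairs, matching the emulated
clinical cohort; stratified five-fold splits then give 80/60
(normal/fracture) training and 20/15 test partitions per fold.

The phantom deliberately has minimal realism: it supplies localized,
oriented contrast deficits inside a textured blob — the statistical
structure the detector and classifier need — not anatomy, projection
physics, or the artifact spectrum of real radiographs.  Passing the
synthetic study therefore demonstrates that the pipeline's mechanics work
end to end (localization, cross-view fusion, oriented regression,
rescoring, bookkeeping), not that the system would reach clinical
performance on real wrists.

## Scales and parameters

Two configurations ship with the package:

* **Clinical-scale defaults** (`default_run_config`): stage-1 input
  1400×1200, SGD with lr 0.001, momentum 0.9, weight decay 1e-4, 5000
  iterations, batch 1; stage-2 crops 256×256, Adam with lr 1e-4, weight
  decay 1e-4, 1500 iterations, batch 12; stage-2 anchors with aspect ratios
  1/1.15/2/2.25/3, scales 2^(i/5) (i = 0..4) and per-level sizes 9/4/1 px;
  CLAHE clip 2.0 with an 8×8 tile grid; augmentation by joint horizontal
  flip and per-view contrast jitter.

* **Desk-scale study** (`scaled_run_config`, used by the test-suite and the
  acceptance script): 192×192 phantom frames with a ~50 px scaphoid,
  stage-1 input 96×96 (anchor bases 16/24/32), stage-2 crops 64×64.  The
  anchor menu uses ratios 0.25/0.4/1/2.5/4 with scales 1/1.4 — after
  long-edge normalization a bar can be elongated either horizontally
  (w/h > 1) or vertically (w/h < 1), so the menu must contain reciprocal
  ratio pairs; squares catch strongly diagonal bars via containment.
  Training runs 1500 iterations at batch 6 with Adam lr 3e-4 and weight
  decay 2e-3: without pretrained weights the tiny backbone must learn from
  120 pairs, which needs both a faster rate than the clinical-scale
  schedule and noticeably stronger shrinkage to generalize.  Stage 1 runs
  1200 iterations at lr 3e-4.  A global gradient-norm clip of 20 stabilizes
  the N_pos-normalized losses, whose magnitude is large early in training.
  CLAHE on 64 px crops uses a 2×2 tile grid so the equalization kernel
  stays ~32 px as at clinical scale — an 8×8 grid would equalize 8 px
  tiles and mostly amplify noise.

The desk-scale study trains on 120 pairs (52 fracture / 68 normal — one
fold's worth of the cohort composition) and evaluates on 40 held-out pairs
(18/22); these sizes are the package's chosen study conditions.

## Evaluation

Classification uses the standard confusion-matrix metrics; accuracy is
(TP+TN)/total.  Ratios with empty denominators are reported as flagged
nulls, never as silent zeros.  Detection is evaluated subject-level: a
fracture subject is a true positive when any retained detection overlaps a
truth box at the match IoU (default 0.2); a normal subject is a false
positive when anything is retained; the mean IoU averages each fracture
subject's best retained overlap (0 when nothing is retained).  The
acceptance study additionally reports the per-subject best retained
overlap across *both* views: the fracture is one physical event observed
in two projections, and the better-localized projection is what a reader
would be pointed to.  Pipeline-level detection metrics are computed in
full-frame coordinates by mapping retained detections back through the
crop transform, which makes oracle-crop and detector-crop runs directly
comparable.

The single-view baseline is the degenerate configuration of the same code
path: the lateral input is blanked (zero image) during both training and
evaluation, so the fusion module carries AP information only.  Comparing
its recall with the multi-view model isolates what the second view
contributes; the expected gap comes from fracture subjects whose bar is
occult in the AP view.

## Numerical choices and degenerate inputs

* Probabilities are clamped at 1e-7 before logarithms; the fusion term uses
  the fused log-softmax form whose gradient (softmax − onehot) survives
  saturation.
* N_pos = 0 (normal images) is guarded with max(N_pos, 1); the regression
  loss is exactly 0 with no positives.
* Rotated IoU is exact convex-polygon arithmetic (shapely); anchor
  assignment prefilters candidates by axis-aligned overlap with the ground
  truth's bounding box, which cannot discard any anchor of nonzero rotated
  overlap.
* NMS ties (equal scores) keep the lower input index; all stochastic
  components consume explicit seeds; a constant image passes CLAHE
  unchanged (no histogram spread to equalize).
* Resizing a rotated box anisotropically cannot yield a rectangle; the
  minimum-area rotated rectangle is re-fit to the affinely scaled corners
  (exact under uniform scaling).
* Stage-1 boxes degenerate after image-boundary clipping are discarded; if
  nothing clears the score floor the locator raises an explicit
  not-found error rather than returning an empty result.

## Known limitations

* The phantom's backgrounds are stationary in style; real radiographs vary
  in exposure, positioning and anatomy far more, and no claim about
  clinical performance follows from the synthetic study.
* At the 64 px desk scale a fracture bar is 2–4 px wide, so oriented-box
  IoU is extremely sensitive to one-pixel height errors; localization
  figures at this scale are structurally lower than what the same
  architecture could reach on 256 px crops.
* The full backbone profile replicates a deep residual layout but trains
  from scratch; loading published pretrained weights is out of scope.
* The LA view is rendered with deliberate partial occlusion, and its
  detection metrics sit below the AP view's — consistent with the
  occluded-lateral reading problem the system targets.
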