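"""Synthetic paired AP/LA wrist phantoms with known ground truth.

Each subject is a latent "fracture event" (or its absence) rendered into two
grayscale projections: a low-frequency bone-texture background, a bright
elliptical scaphoid blob with neighboring distractor blobs (the lateral view
gets an extra occluding blob), and — for fracture subjects — a dark, thin,
rotated bar whose minimum-area rectangle is the oriented ground-truth box.
The same latent event drives both views with correlated position and
independent per-view contrast; an "occult" fraction of fracture subjects
renders the bar at near-background contrast in one randomly chosen view.

The phantom is deliberately minimal: it provides the statistical structure
detection and classification need (localized oriented contrast deficits in a
textured blob), not radiographic realism.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import AxisBox, OrientedBox, normalize_angle
from .imaging import ImageRecord, ViewPairRecord, resize_image, write_manifest

__all__ = [
    "PhantomConfig", "PhantomTruth", "CropTransform",
    "generate_cohort", "render_view", "make_crop_dataset", "save_cohort",
]

log = logging.getLogger(__name__)

SCAPHOID_BUMP = 0.28  # intensity elevation of the scaphoid blob
DISTRACTOR_BUMP = 0.16
OCCULT_CONTRAST = (0.04, 0.10)  # occult bars sit near the noise floor
OCCULT_THRESHOLD = 0.12


@dataclass
class PhantomConfig:
    """Cohort composition and rendering parameters.

    Defaults mirror the emulated clinical cohort: 100 normal and 75 fracture
    subject pairs, with 15% of fracture subjects occult in one view (the
    midpoint of the cited 7-21% occult prevalence).  Frames are rendered at
    a reduced 192x192 resolution with the scaphoid at ~a quarter of the
    frame, keeping the geometry proportional to clinical wrist films.
    """

    n_fracture: int = 75
    n_normal: int = 100
    image_size: tuple[int, int] = (192, 192)  # (width, height)
    scaphoid_size_range: tuple[float, float] = (44.0, 60.0)
    fracture_length_range: tuple[float, float] = (16.0, 30.0)
    fracture_width_range: tuple[float, float] = (3.0, 6.0)
    fracture_contrast_range: tuple[float, float] = (0.35, 0.75)
    occult_fraction: float = 0.15
    noise_sigma: float = 0.02
    bone_density_range: tuple[float, float] = (0.25, 0.45)
    la_occlusion_strength: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_fracture < 0 or self.n_normal < 0:
            raise ValueError("cohort counts must be non-negative")
        if min(self.image_size) <= 0:
            raise ValueError("image size must be positive")
        if not 0.0 <= self.occult_fraction <= 1.0:
            raise ValueError("occult_fraction must lie in [0, 1]")
        for name in ("scaphoid_size_range", "fracture_length_range",
                     "fracture_width_range", "fracture_contrast_range",
                     "bone_density_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")


@dataclass
class ViewTruth:
    scaphoid_box: AxisBox
    fracture_boxes: list[OrientedBox]
    params: dict


@dataclass
class PhantomTruth:
    subject_id: str
    label: str
    occult: bool
    views: dict[str, ViewTruth] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "label": self.label,
            "occult": self.occult,
            "views": {
                v: {
                    "scaphoid_box": t.scaphoid_box.to_json(),
                    "fracture_boxes": [b.to_json() for b in t.fracture_boxes],
                    "params": t.params,
                }
                for v, t in self.views.items()
            },
        }


def _ellipse_field(shape: tuple[int, int], cx: float, cy: float, a: float,
                   b: float, phi: float) -> np.ndarray:
    """Normalized elliptical radius field (1 on the ellipse boundary)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    c, s = math.cos(phi), math.sin(phi)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def _soft_blob(shape, cx, cy, a, b, phi, edge: float = 0.16) -> np.ndarray:
    r = _ellipse_field(shape, cx, cy, a, b, phi)
    return np.clip((1.0 + edge / 2 - r) / edge, 0.0, 1.0)


def _bar_mask(shape: tuple[int, int], box: OrientedBox,
              edge: float = 0.8) -> np.ndarray:
    """Soft-edged mask of a rotated rectangle (support ~ the box itself)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dx, dy = xx - box.cx, yy - box.cy
    c, s = math.cos(box.theta), math.sin(box.theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    mu = np.clip((box.w / 2 - np.abs(u)) / edge + 0.5, 0.0, 1.0)
    mv = np.clip((box.h / 2 - np.abs(v)) / edge + 0.5, 0.0, 1.0)
    return mu * mv


def _draw_subject(rng: np.random.Generator, config: PhantomConfig,
                  fracture: bool, occult: bool) -> dict:
    """Draw the latent parameters shared by and specialized per view."""
    w, h = config.image_size
    size = rng.uniform(*config.scaphoid_size_range)
    a = size / 2.0
    params: dict = {"views": {}}
    # shared latent fracture event (relative position/orientation in the blob)
    if fracture:
        params["rel_pos"] = rng.uniform(-0.3, 0.3, size=2).tolist()
        params["psi"] = float(rng.uniform(-math.pi, math.pi))
        params["length"] = float(rng.uniform(*config.fracture_length_range))
        params["width"] = float(rng.uniform(*config.fracture_width_range))
        params["occult_view"] = ("AP", "LA")[int(rng.integers(2))] if occult else None
    for view in ("AP", "LA"):
        b = a * rng.uniform(0.70, 0.92)
        phi = rng.uniform(-math.pi / 2, math.pi / 2)
        cx = w / 2 + rng.uniform(-0.12, 0.12) * w
        cy = h / 2 + rng.uniform(-0.12, 0.12) * h
        vp = {
            "cx": cx, "cy": cy, "a": a, "b": b, "phi": phi,
            "density": float(rng.uniform(*config.bone_density_range)),
            "texture": rng.uniform(-1, 1, size=(5, 5)).tolist(),
            "noise_seed": int(rng.integers(2**31 - 1)),
        }
        # distractor blobs around the scaphoid
        distractors = []
        for _ in range(2):
            ang = rng.uniform(0, 2 * math.pi)
            dist = rng.uniform(1.3, 1.9) * a
            distractors.append({
                "cx": cx + dist * math.cos(ang), "cy": cy + dist * math.sin(ang),
                "a": a * rng.uniform(0.5, 0.9), "b": b * rng.uniform(0.5, 0.9),
                "phi": rng.uniform(-math.pi / 2, math.pi / 2),
                "bump": DISTRACTOR_BUMP,
            })
        if view == "LA" and config.la_occlusion_strength > 0:
            ang = rng.uniform(0, 2 * math.pi)
            dist = rng.uniform(0.7, 1.0) * a
            distractors.append({
                "cx": cx + dist * math.cos(ang), "cy": cy + dist * math.sin(ang),
                "a": a * 0.7, "b": b * 0.7,
                "phi": rng.uniform(-math.pi / 2, math.pi / 2),
                "bump": DISTRACTOR_BUMP * config.la_occlusion_strength / 0.5,
            })
        vp["distractors"] = distractors
        if fracture:
            if occult and params["occult_view"] == view:
                vp["contrast"] = float(rng.uniform(*OCCULT_CONTRAST))
            else:
                vp["contrast"] = float(rng.uniform(*config.fracture_contrast_range))
            vp["pos_jitter"] = rng.uniform(-0.1, 0.1, size=2).tolist()
            vp["angle_jitter"] = float(rng.uniform(-0.17, 0.17))
        params["views"][view] = vp
    return params


def _view_truth(params: dict, view: str, config: PhantomConfig,
                fracture: bool) -> ViewTruth:
    vp = params["views"][view]
    w, h = config.image_size
    cx, cy, a, b, phi = vp["cx"], vp["cy"], vp["a"], vp["b"], vp["phi"]
    # bounding box of the rotated ellipse
    c, s = math.cos(phi), math.sin(phi)
    ex = math.hypot(a * c, b * s)
    ey = math.hypot(a * s, b * c)
    sb = AxisBox(max(0.0, cx - ex), max(0.0, cy - ey),
                 min(w - 1.0, cx + ex), min(h - 1.0, cy + ey))
    boxes: list[OrientedBox] = []
    if fracture:
        u = params["rel_pos"][0] + vp["pos_jitter"][0] * 0.3
        v = params["rel_pos"][1] + vp["pos_jitter"][1] * 0.3
        bx = cx + (u * a) * c - (v * b) * s
        by = cy + (u * a) * s + (v * b) * c
        psi = params["psi"] + vp["angle_jitter"]
        length = min(params["length"], 1.5 * a * (1.0 - max(abs(u), abs(v))))
        length = max(length, config.fracture_length_range[0] * 0.6)
        bar = normalize_angle(OrientedBox(bx, by, length, params["width"], psi))
        # keep the bar inside the scaphoid box (shrink if a corner pokes out)
        for _ in range(8):
            corners = bar.corners()
            if (corners[:, 0].min() >= sb.x_min and corners[:, 0].max() <= sb.x_max
                    and corners[:, 1].min() >= sb.y_min
                    and corners[:, 1].max() <= sb.y_max):
                break
            bar = normalize_angle(OrientedBox(
                0.7 * bar.cx + 0.3 * cx, 0.7 * bar.cy + 0.3 * cy,
                max(bar.w * 0.85, 6.0), bar.h, bar.theta))
        boxes.append(bar)
    return ViewTruth(sb, boxes, vp)


def render_view(truth: ViewTruth, view: str, config: PhantomConfig) -> np.ndarray:
    """Render one projection as a float image in [0, 1]."""
    w, h = config.image_size
    vp = truth.params
    shape = (h, w)
    tex = np.asarray(vp["texture"])
    img = vp["density"] + 0.06 * ndimage.zoom(tex, (h / tex.shape[0], w / tex.shape[1]),
                                              order=3, prefilter=False)
    img = img + SCAPHOID_BUMP * _soft_blob(shape, vp["cx"], vp["cy"],
                                           vp["a"], vp["b"], vp["phi"])
    for d in vp["distractors"]:
        img = img + d["bump"] * _soft_blob(shape, d["cx"], d["cy"],
                                           d["a"], d["b"], d["phi"])
    for bar in truth.fracture_boxes:
        depth = vp["contrast"] * SCAPHOID_BUMP
        img = img - depth * _bar_mask(shape, bar)
    rng = np.random.default_rng(vp["noise_seed"])
    img = img + rng.normal(0.0, config.noise_sigma, size=shape)
    return np.clip(img, 0.0, 1.0)


def _to_record(subject_id: str, view: str, img01: np.ndarray) -> ImageRecord:
    return ImageRecord(subject_id, view,
                       np.clip(np.rint(img01 * 255), 0, 255).astype(np.uint8), 8)


def generate_cohort(config: PhantomConfig
                    ) -> tuple[list[ViewPairRecord], list[PhantomTruth]]:
    """Generate exactly ``n_fracture + n_normal`` paired subjects.

    Deterministic per ``config.seed``; class counts are exact.  Fracture
    subjects share one latent event across views; a seeded subset of them is
    occult (near-background contrast) in one randomly chosen view.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_fracture + config.n_normal
    # choose the occult subset of fracture subjects deterministically
    n_occult = int(round(config.occult_fraction * config.n_fracture))
    occult_ids = set(rng.choice(config.n_fracture, size=n_occult, replace=False)
                     .tolist()) if config.n_fracture else set()
    records, truths = [], []
    for i in range(n_total):
        fracture = i < config.n_fracture
        occult = fracture and (i in occult_ids)
        sid = f"subj_{i:03d}"
        sub_rng = np.random.default_rng(np.random.SeedSequence([config.seed, i]))
        params = _draw_subject(sub_rng, config, fracture, occult)
        truth = PhantomTruth(sid, "fracture" if fracture else "normal", occult)
        imgs = {}
        for view in ("AP", "LA"):
            vt = _view_truth(params, view, config, fracture)
            truth.views[view] = vt
            imgs[view] = _to_record(sid, view, render_view(vt, view, config))
        records.append(ViewPairRecord(
            sid, imgs["AP"], imgs["LA"], truth.label,
            list(truth.views["AP"].fracture_boxes),
            list(truth.views["LA"].fracture_boxes),
            truth.views["AP"].scaphoid_box, truth.views["LA"].scaphoid_box))
        truths.append(truth)
    return records, truths


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropTransform:
    """Maps between full-frame and crop coordinates for one view."""

    x0: float
    y0: float
    scale_x: float
    scale_y: float

    def map_box(self, box: OrientedBox) -> OrientedBox:
        return normalize_angle(OrientedBox(
            (box.cx - self.x0) * self.scale_x, (box.cy - self.y0) * self.scale_y,
            box.w * self.scale_x, box.h * self.scale_y, box.theta))

    def unmap_box(self, box: OrientedBox) -> OrientedBox:
        return normalize_angle(OrientedBox(
            box.cx / self.scale_x + self.x0, box.cy / self.scale_y + self.y0,
            box.w / self.scale_x, box.h / self.scale_y, box.theta))


def _crop_view(img: ImageRecord, scaphoid: AxisBox, boxes: list[OrientedBox],
               margin: float, crop_size: int
               ) -> tuple[ImageRecord, list[OrientedBox], CropTransform]:
    side = max(scaphoid.w, scaphoid.h) * (1.0 + 2.0 * margin)
    side = int(round(max(side, 8)))
    x0 = int(round(scaphoid.cx - side / 2))
    y0 = int(round(scaphoid.cy - side / 2))
    x0 = min(max(x0, 0), max(img.width - side, 0))
    y0 = min(max(y0, 0), max(img.height - side, 0))
    x1 = min(x0 + side, img.width)
    y1 = min(y0 + side, img.height)
    crop = img.pixels[y0:y1, x0:x1]
    cropped = ImageRecord(img.subject_id, img.view, crop, img.bit_depth)
    shifted = [normalize_angle(OrientedBox(b.cx - x0, b.cy - y0, b.w, b.h, b.theta))
               for b in boxes]
    resized, out_boxes, _ = resize_image(cropped, (crop_size, crop_size), shifted)
    tf = CropTransform(float(x0), float(y0),
                       crop_size / crop.shape[1], crop_size / crop.shape[0])
    return resized, out_boxes, tf


def make_crop_dataset(records: list[ViewPairRecord], crop_margin: float = 0.25,
                      crop_size: int = 256
                      ) -> tuple[list[ViewPairRecord], dict[str, dict[str, CropTransform]]]:
    """Cut square scaphoid crops (expanded by ``crop_margin``) from both views
    and resize them to ``crop_size`` squares, remapping fracture boxes.

    Returns the crop records plus per-subject, per-view transforms for
    mapping detections back to full-frame coordinates.  Records without a
    usable scaphoid box in either view are skipped with a logged warning.
    """
    out, transforms = [], {}
    for rec in records:
        if rec.ap_scaphoid_box is None or rec.la_scaphoid_box is None \
                or min(rec.ap_scaphoid_box.w, rec.ap_scaphoid_box.h) < 2 \
                or min(rec.la_scaphoid_box.w, rec.la_scaphoid_box.h) < 2:
            log.warning("skipping %s: degenerate or missing scaphoid box",
                        rec.subject_id)
            continue
        ap, ap_boxes, ap_tf = _crop_view(rec.ap, rec.ap_scaphoid_box,
                                         rec.ap_fracture_boxes, crop_margin, crop_size)
        la, la_boxes, la_tf = _crop_view(rec.la, rec.la_scaphoid_box,
                                         rec.la_fracture_boxes, crop_margin, crop_size)
        out.append(ViewPairRecord(rec.subject_id, ap, la, rec.label,
                                  ap_boxes, la_boxes, None, None))
        transforms[rec.subject_id] = {"AP": ap_tf, "LA": la_tf}
    return out, transforms


def save_cohort(records: list[ViewPairRecord], truths: list[PhantomTruth],
                out_dir: str | Path) -> None:
    """Write images + manifest JSON + ground-truth JSON under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest(records, out_dir / "manifest.json")
    (out_dir / "truth.json").write_text(
        json.dumps([t.to_json() for t in truths], indent=1))
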