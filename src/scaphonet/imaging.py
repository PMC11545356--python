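"""Radiograph I/O, CLAHE contrast enhancement, resizing and paired-view
augmentation, plus the JSON dataset manifest.

Images are 2-D grayscale arrays (8- or 16-bit) wrapped in
:class:`ImageRecord`; a subject's AP and LA projections travel together in a
:class:`ViewPairRecord` so augmentation can keep the two views anatomically
consistent (a single horizontal-flip draw is applied to both).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import exposure, transform

from .geometry import AxisBox, OrientedBox, normalize_angle, oriented_from_points

__all__ = [
    "ImageRecord", "ViewPairRecord", "PreprocessConfig", "ManifestError",
    "apply_clahe", "resize_image", "augment_pair",
    "read_manifest", "write_manifest",
]

VIEWS = ("AP", "LA")
LABELS = ("fracture", "normal")


class ManifestError(ValueError):
    """Schema violation in a dataset manifest, naming the offending record."""


@dataclass
class ImageRecord:
    subject_id: str
    view: str  # "AP" | "LA"
    pixels: np.ndarray  # (H, W) uint8 or uint16
    bit_depth: int = 8

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale array")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError("image smaller than 16x16")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class ViewPairRecord:
    subject_id: str
    ap: ImageRecord
    la: ImageRecord
    label: str  # "fracture" | "normal"
    ap_fracture_boxes: list[OrientedBox] = field(default_factory=list)
    la_fracture_boxes: list[OrientedBox] = field(default_factory=list)
    ap_scaphoid_box: AxisBox | None = None
    la_scaphoid_box: AxisBox | None = None

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        has_boxes = bool(self.ap_fracture_boxes or self.la_fracture_boxes)
        if (self.label == "fracture") != has_boxes:
            raise ValueError(
                f"{self.subject_id}: label {self.label!r} inconsistent with "
                f"fracture box count")
        for img, boxes in ((self.ap, self.ap_fracture_boxes),
                           (self.la, self.la_fracture_boxes)):
            for b in boxes:
                xs, ys = b.corners()[:, 0], b.corners()[:, 1]
                if xs.min() < -0.5 or ys.min() < -0.5 \
                        or xs.max() > img.width - 0.5 or ys.max() > img.height - 0.5:
                    raise ValueError(f"{self.subject_id}: fracture box outside image")


@dataclass
class PreprocessConfig:
    """Preprocessing defaults for the two stages.

    ``stage1_size`` / ``stage2_size`` are (width, height).  The CLAHE clip is
    expressed in the conventional multiples-of-uniform-histogram units and is
    mapped internally onto scikit-image's normalized clip limit (clip / 100).
    """

    stage1_size: tuple[int, int] = (1400, 1200)
    stage2_size: tuple[int, int] = (256, 256)
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    contrast_jitter_range: tuple[float, float] = (0.8, 1.2)
    hflip_probability: float = 0.5

    def __post_init__(self):
        if min(self.stage1_size) <= 0 or min(self.stage2_size) <= 0:
            raise ValueError("target sizes must be positive")
        lo, hi = self.contrast_jitter_range
        if not (lo <= 1.0 <= hi):
            raise ValueError("contrast jitter interval must contain 1")


def apply_clahe(img: ImageRecord, clip: float = 2.0,
                tiles: tuple[int, int] = (8, 8)) -> ImageRecord:
    """Contrast-limited adaptive histogram equalization.

    Deterministic; preserves shape and bit depth.  Constant images are
    returned unchanged (there is no histogram spread to equalize).
    """
    if clip <= 0:
        raise ValueError("CLAHE clip must be positive")
    px = img.pixels
    if px.min() == px.max():
        return replace(img, pixels=px.copy())
    norm = px.astype(np.float64) / img.max_value
    kernel = (max(1, img.height // tiles[0]), max(1, img.width // tiles[1]))
    eq = exposure.equalize_adapthist(norm, kernel_size=kernel,
                                     clip_limit=clip / 100.0)
    out = np.clip(np.rint(eq * img.max_value), 0, img.max_value)
    return replace(img, pixels=out.astype(px.dtype))


def _scale_axis_box(box: AxisBox, sx: float, sy: float) -> AxisBox:
    return AxisBox(box.x_min * sx, box.y_min * sy, box.x_max * sx, box.y_max * sy)


def _scale_oriented_box(box: OrientedBox, sx: float, sy: float) -> OrientedBox:
    if math.isclose(sx, sy):
        return normalize_angle(
            OrientedBox(box.cx * sx, box.cy * sy, box.w * sx, box.h * sx, box.theta))
    corners = box.corners() * np.array([sx, sy])
    return oriented_from_points(corners)


def resize_image(img: ImageRecord, target: tuple[int, int],
                 oriented_boxes: list[OrientedBox] | None = None,
                 axis_boxes: list[AxisBox] | None = None,
                 ) -> tuple[ImageRecord, list[OrientedBox], list[AxisBox]]:
    """Bilinear resize to ``target`` (width, height), transforming boxes.

    Axis boxes scale per axis.  Oriented boxes under anisotropic scaling no
    longer map to rectangles, so the minimum-area rotated rectangle is
    re-fit to the affinely scaled corners.
    """
    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError("resize target must be positive")
    sx, sy = tw / img.width, th / img.height
    if (tw, th) == (img.width, img.height):
        out = replace(img, pixels=img.pixels.copy())
        return out, list(oriented_boxes or []), list(axis_boxes or [])
    resized = transform.resize(img.pixels.astype(np.float64), (th, tw), order=1,
                               mode="edge", anti_aliasing=False,
                               preserve_range=True)
    resized = np.clip(np.rint(resized), 0, img.max_value).astype(img.pixels.dtype)
    out = replace(img, pixels=resized)
    obs = [_scale_oriented_box(b, sx, sy) for b in (oriented_boxes or [])]
    abs_ = [_scale_axis_box(b, sx, sy) for b in (axis_boxes or [])]
    return out, obs, abs_


def _flip_image(img: ImageRecord) -> ImageRecord:
    return replace(img, pixels=img.pixels[:, ::-1].copy())


def _flip_oriented(box: OrientedBox, width: int) -> OrientedBox:
    return normalize_angle(
        OrientedBox(width - 1 - box.cx, box.cy, box.w, box.h, -box.theta))


def _flip_axis(box: AxisBox, width: int) -> AxisBox:
    return AxisBox(width - 1 - box.x_max, box.y_min, width - 1 - box.x_min, box.y_max)


def _jitter_contrast(img: ImageRecord, factor: float) -> ImageRecord:
    px = img.pixels.astype(np.float64)
    mean = px.mean()
    out = np.clip(np.rint((px - mean) * factor + mean), 0, img.max_value)
    return replace(img, pixels=out.astype(img.pixels.dtype))


def augment_pair(pair: ViewPairRecord, config: PreprocessConfig,
                 seed: int) -> ViewPairRecord:
    """Jointly augment the AP/LA pair: one horizontal-flip draw applied to
    both views (the fusion module assumes corresponding anatomy) and an
    independent multiplicative contrast jitter about each view's mean.
    Fully reproducible from ``seed``; preserves label and box counts.
    """
    rng = np.random.default_rng(seed)
    do_flip = rng.random() < config.hflip_probability
    lo, hi = config.contrast_jitter_range
    f_ap = rng.uniform(lo, hi)
    f_la = rng.uniform(lo, hi)
    ap, la = pair.ap, pair.la
    ap_fb, la_fb = list(pair.ap_fracture_boxes), list(pair.la_fracture_boxes)
    ap_sb, la_sb = pair.ap_scaphoid_box, pair.la_scaphoid_box
    if do_flip:
        ap, la = _flip_image(ap), _flip_image(la)
        ap_fb = [_flip_oriented(b, ap.width) for b in ap_fb]
        la_fb = [_flip_oriented(b, la.width) for b in la_fb]
        ap_sb = _flip_axis(ap_sb, ap.width) if ap_sb else None
        la_sb = _flip_axis(la_sb, la.width) if la_sb else None
    ap = _jitter_contrast(ap, f_ap)
    la = _jitter_contrast(la, f_la)
    return ViewPairRecord(pair.subject_id, ap, la, pair.label,
                          ap_fb, la_fb, ap_sb, la_sb)


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def _view_to_json(img: ImageRecord, boxes: list[OrientedBox],
                  scaphoid: AxisBox | None, image_dir: Path,
                  manifest_dir: Path) -> dict:
    rel = Path("images") / f"{img.subject_id}_{img.view}.png"
    path = manifest_dir / rel
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, img.pixels)
    return {
        "image": str(rel),
        "bit_depth": img.bit_depth,
        "fracture_boxes": [b.to_json() for b in boxes],
        "scaphoid_box": scaphoid.to_json() if scaphoid else None,
    }


def write_manifest(records: list[ViewPairRecord], path: str | Path) -> None:
    """Write a dataset manifest (JSON) plus PNG images next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest_dir = path.parent
    payload = {"records": []}
    for rec in records:
        payload["records"].append({
            "subject_id": rec.subject_id,
            "label": rec.label,
            "ap": _view_to_json(rec.ap, rec.ap_fracture_boxes,
                                rec.ap_scaphoid_box, manifest_dir, manifest_dir),
            "la": _view_to_json(rec.la, rec.la_fracture_boxes,
                                rec.la_scaphoid_box, manifest_dir, manifest_dir),
        })
    path.write_text(json.dumps(payload, indent=1))


def _view_from_json(obj: dict, subject_id: str, view: str,
                    manifest_dir: Path) -> tuple[ImageRecord, list[OrientedBox], AxisBox | None]:
    if obj is None:
        raise ManifestError(f"{subject_id}: missing {view} view")
    pixels = np.asarray(iio.imread(manifest_dir / obj["image"]))
    bit_depth = int(obj.get("bit_depth", 8 if pixels.dtype == np.uint8 else 16))
    img = ImageRecord(subject_id, view, pixels, bit_depth)
    boxes = [OrientedBox.from_json(b) for b in obj.get("fracture_boxes", [])]
    sb = obj.get("scaphoid_box")
    return img, boxes, AxisBox.from_json(sb) if sb else None


def read_manifest(path: str | Path) -> list[ViewPairRecord]:
    """Read a manifest; image paths resolve relative to the manifest file.

    Schema errors (missing view, unknown label, out-of-bounds box) raise
    :class:`ManifestError` naming the record.
    """
    path = Path(path)
    payload = json.loads(path.read_text())
    records = []
    for obj in payload.get("records", []):
        sid = obj.get("subject_id", "<unnamed>")
        try:
            ap, ap_fb, ap_sb = _view_from_json(obj.get("ap"), sid, "AP", path.parent)
            la, la_fb, la_sb = _view_from_json(obj.get("la"), sid, "LA", path.parent)
            records.append(ViewPairRecord(sid, ap, la, obj.get("label", ""),
                                          ap_fb, la_fb, ap_sb, la_sb))
        except ManifestError:
            raise
        except (ValueError, KeyError) as exc:
            raise ManifestError(f"record {sid}: {exc}") from exc
    return records
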