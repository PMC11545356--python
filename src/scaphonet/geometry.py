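"""Oriented and axis-aligned box geometry.

An oriented fracture box is parameterized by center, side lengths and a
rotation angle of its first side from the image x-axis (counter-clockwise
positive, 0-based pixel-center coordinates).  The angle convention is the
"long-edge" one used for angle regression: after normalization ``theta``
lies in the half-open interval (-pi/4, pi/4], which makes the linear angle
code ``t_theta = 4*theta/pi`` and the tanh-bounded prediction share the
range [-1, 1].  Anchors are axis-aligned (angle 0).

Rotated-polygon intersection uses shapely; everything else is numpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import MultiPoint, Polygon

__all__ = [
    "OrientedBox", "AxisBox", "BoxDelta", "AnchorGrid", "InvalidBoxError",
    "normalize_angle", "encode_box", "decode_box", "rotated_iou",
    "nms_rotated", "nms_axis", "build_anchor_grid",
    "encode_boxes", "decode_deltas", "oriented_from_points", "axis_iou_matrix",
]

HALF_PI = math.pi / 2.0
QUARTER_PI = math.pi / 4.0


class InvalidBoxError(ValueError):
    """Raised for boxes with non-positive side lengths."""


@dataclass(frozen=True)
class OrientedBox:
    """Rotated rectangle: center (cx, cy), sides (w, h), angle theta [rad]."""

    cx: float
    cy: float
    w: float
    h: float
    theta: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise InvalidBoxError(f"non-positive box sides w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def corners(self) -> np.ndarray:
        """4x2 corner array; the corner mean reproduces the center."""
        c, s = math.cos(self.theta), math.sin(self.theta)
        hw, hh = self.w / 2.0, self.h / 2.0
        local = np.array([[-hw, -hh], [hw, -hh], [hw, hh], [-hw, hh]])
        rot = np.array([[c, -s], [s, c]])
        return local @ rot.T + np.array([self.cx, self.cy])

    def polygon(self) -> Polygon:
        return Polygon(self.corners())

    def to_json(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "w": self.w, "h": self.h,
                "theta_rad": self.theta}

    @classmethod
    def from_json(cls, obj: dict) -> "OrientedBox":
        return cls(obj["cx"], obj["cy"], obj["w"], obj["h"], obj["theta_rad"])


@dataclass(frozen=True)
class AxisBox:
    """Axis-aligned box in corner form (x_max > x_min, y_max > y_min)."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise InvalidBoxError(f"degenerate axis box {self}")

    @property
    def cx(self) -> float:
        return (self.x_min + self.x_max) / 2.0

    @property
    def cy(self) -> float:
        return (self.y_min + self.y_max) / 2.0

    @property
    def w(self) -> float:
        return self.x_max - self.x_min

    @property
    def h(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_center(cls, cx: float, cy: float, w: float, h: float) -> "AxisBox":
        return cls(cx - w / 2.0, cy - h / 2.0, cx + w / 2.0, cy + h / 2.0)

    def as_oriented(self) -> OrientedBox:
        return OrientedBox(self.cx, self.cy, self.w, self.h, 0.0)

    def to_json(self) -> dict:
        return {"x_min": self.x_min, "y_min": self.y_min,
                "x_max": self.x_max, "y_max": self.y_max}

    @classmethod
    def from_json(cls, obj: dict) -> "AxisBox":
        return cls(obj["x_min"], obj["y_min"], obj["x_max"], obj["y_max"])


@dataclass(frozen=True)
class BoxDelta:
    """Regression 5-vector (tx, ty, tw, th, ttheta) relative to an anchor."""

    tx: float
    ty: float
    tw: float
    th: float
    ttheta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tw, self.th, self.ttheta])


def normalize_angle(box: OrientedBox) -> OrientedBox:
    """Return an equal-point-set box with theta in (-pi/4, pi/4].

    A rectangle is invariant under theta -> theta + pi and, with sides
    swapped, under theta -> theta + pi/2; both symmetries are applied until
    the angle lands in the canonical interval.
    """
    w, h, theta = box.w, box.h, box.theta
    theta = math.remainder(theta, math.pi)  # -> (-pi/2, pi/2] up to sign of .5ulp
    if theta > QUARTER_PI:
        theta -= HALF_PI
        w, h = h, w
    elif theta <= -QUARTER_PI:
        theta += HALF_PI
        w, h = h, w
    return OrientedBox(box.cx, box.cy, w, h, theta)


def encode_box(gt: OrientedBox, anchor: AxisBox) -> BoxDelta:
    """Encode a normalized oriented box against an axis-aligned anchor.

    Offsets are anchor-size-relative, scales are logarithmic and the angle
    code is the linear map ``4*theta/pi`` onto [-1, 1].
    """
    return BoxDelta(
        tx=(gt.cx - anchor.cx) / anchor.w,
        ty=(gt.cy - anchor.cy) / anchor.h,
        tw=math.log(gt.w / anchor.w),
        th=math.log(gt.h / anchor.h),
        ttheta=4.0 * gt.theta / math.pi,
    )


def decode_box(delta: BoxDelta, anchor: AxisBox) -> OrientedBox:
    """Exact right-inverse of :func:`encode_box`.

    Raw network angle outputs must be squashed with ``tanh`` *before* this
    call; ``delta.ttheta`` is the bounded code in [-1, 1].
    """
    return OrientedBox(
        cx=anchor.cx + delta.tx * anchor.w,
        cy=anchor.cy + delta.ty * anchor.h,
        w=anchor.w * math.exp(delta.tw),
        h=anchor.h * math.exp(delta.th),
        theta=math.pi * delta.ttheta / 4.0,
    )


# -- vectorized forms used by training / inference --------------------------

def encode_boxes(gt: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Vectorized encode: gt (M,5) center-form rows, anchors (M,4) center-form."""
    out = np.empty((gt.shape[0], 5))
    out[:, 0] = (gt[:, 0] - anchors[:, 0]) / anchors[:, 2]
    out[:, 1] = (gt[:, 1] - anchors[:, 1]) / anchors[:, 3]
    out[:, 2] = np.log(gt[:, 2] / anchors[:, 2])
    out[:, 3] = np.log(gt[:, 3] / anchors[:, 3])
    out[:, 4] = 4.0 * gt[:, 4] / math.pi
    return out


def decode_deltas(deltas: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Vectorized decode to (M,5) center-form oriented rows (cx,cy,w,h,theta)."""
    out = np.empty_like(deltas, dtype=np.float64)
    out[:, 0] = anchors[:, 0] + deltas[:, 0] * anchors[:, 2]
    out[:, 1] = anchors[:, 1] + deltas[:, 1] * anchors[:, 3]
    out[:, 2] = anchors[:, 2] * np.exp(deltas[:, 2])
    out[:, 3] = anchors[:, 3] * np.exp(deltas[:, 3])
    out[:, 4] = math.pi * deltas[:, 4] / 4.0
    return out


def rotated_iou(a: OrientedBox, b: OrientedBox) -> float:
    """Exact convex-polygon intersection-over-union of two rotated boxes."""
    pa, pb = a.polygon(), b.polygon()
    inter = pa.intersection(pb).area
    if inter <= 0.0:
        return 0.0
    union = pa.area + pb.area - inter
    return float(inter / union)


def nms_rotated(boxes: Sequence[OrientedBox], scores: Sequence[float],
                iou_threshold: float) -> list[int]:
    """Greedy score-descending rotated NMS; ties keep the lower input index."""
    if len(boxes) != len(scores):
        raise ValueError("boxes and scores length mismatch")
    if not boxes:
        return []
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((np.arange(len(scores)), -scores))
    kept: list[int] = []
    for idx in order:
        if all(rotated_iou(boxes[idx], boxes[k]) <= iou_threshold for k in kept):
            kept.append(int(idx))
    return kept


def nms_axis(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy axis-aligned NMS on (M,4) corner-form rows (vectorized IoU)."""
    if boxes.shape[0] == 0:
        return []
    order = np.lexsort((np.arange(len(scores)), -scores))
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    kept: list[int] = []
    for idx in order:
        if kept:
            ka = boxes[kept]
            ix = np.maximum(0.0, np.minimum(ka[:, 2], boxes[idx, 2])
                            - np.maximum(ka[:, 0], boxes[idx, 0]))
            iy = np.maximum(0.0, np.minimum(ka[:, 3], boxes[idx, 3])
                            - np.maximum(ka[:, 1], boxes[idx, 1]))
            inter = ix * iy
            union = np.maximum(areas[kept] + areas[idx] - inter, 1e-12)
            if np.any(inter / union > iou_threshold):
                continue
        kept.append(int(idx))
    return kept


def axis_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of corner-form rows: a (M,4) x b (N,4) -> (M,N)."""
    ix = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(min=0)
    iy = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(min=0)
    inter = ix * iy
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter)


def oriented_from_points(points: np.ndarray) -> OrientedBox:
    """Minimum-area rotated rectangle of a point set, as a normalized box."""
    rect = MultiPoint([tuple(p) for p in np.asarray(points, dtype=float)]).minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # collinear/degenerate point sets
        raise InvalidBoxError("points do not span a rectangle")
    xy = np.asarray(rect.exterior.coords)[:4]
    e1 = xy[1] - xy[0]
    e2 = xy[2] - xy[1]
    w = float(np.hypot(*e1))
    h = float(np.hypot(*e2))
    cx, cy = xy.mean(axis=0)
    theta = math.atan2(e1[1], e1[0])
    return normalize_angle(OrientedBox(float(cx), float(cy), w, h, theta))


@dataclass
class AnchorGrid:
    """Dense multi-level anchor lattice (axis-aligned, angle 0).

    ``per_level`` holds (M_l, 4) corner-form arrays; ``boxes`` is their
    concatenation.  Anchor centers sit at ``(i + 0.5) * stride`` so every
    center lies on its level's stride lattice.  Per location there are
    ``len(aspect_ratios) * len(scales)`` anchors; side lengths are
    ``base * scale * sqrt(ratio)`` by ``base * scale / sqrt(ratio)`` so the
    area is ratio-invariant at fixed scale.
    """

    level_strides: tuple[int, ...]
    base_sizes: tuple[float, ...]
    aspect_ratios: tuple[float, ...]
    scales: tuple[float, ...]
    per_level: list[np.ndarray] = field(default_factory=list)

    @property
    def anchors_per_location(self) -> int:
        return len(self.aspect_ratios) * len(self.scales)

    @property
    def boxes(self) -> np.ndarray:
        """All anchors, corner form (sum_l M_l, 4)."""
        return (np.concatenate(self.per_level, axis=0)
                if self.per_level else np.zeros((0, 4)))

    @property
    def centers_sizes(self) -> np.ndarray:
        """All anchors, center form (cx, cy, w, h)."""
        b = self.boxes
        out = np.empty_like(b)
        out[:, 0] = (b[:, 0] + b[:, 2]) / 2
        out[:, 1] = (b[:, 1] + b[:, 3]) / 2
        out[:, 2] = b[:, 2] - b[:, 0]
        out[:, 3] = b[:, 3] - b[:, 1]
        return out

    def level_shapes(self, image_size: tuple[int, int]) -> list[tuple[int, int]]:
        w, h = image_size
        return [(h // s, w // s) for s in self.level_strides]


def build_anchor_grid(image_size: tuple[int, int],
                      level_strides: Sequence[int],
                      base_sizes: Sequence[float],
                      aspect_ratios: Sequence[float],
                      scales: Sequence[float]) -> AnchorGrid:
    """Generate the dense anchor grid for an image of (width, height) pixels.

    One anchor per (level location x ratio x scale), ordered (y, x, ratio,
    scale) within each level — the same order the prediction heads use when
    flattening their output maps.
    """
    if len(level_strides) != len(base_sizes):
        raise ValueError("one base size per level stride is required")
    if any(s <= 0 for s in level_strides) or any(b <= 0 for b in base_sizes):
        raise ValueError("strides and base sizes must be positive")
    width, height = image_size
    grid = AnchorGrid(tuple(level_strides), tuple(base_sizes),
                      tuple(aspect_ratios), tuple(scales))
    # per-location (w, h) menu, ordered ratio-major then scale
    for stride, base in zip(level_strides, base_sizes):
        ny, nx = height // stride, width // stride
        wh = np.array([
            (base * sc * math.sqrt(r), base * sc / math.sqrt(r))
            for r in aspect_ratios for sc in scales
        ])
        if ny == 0 or nx == 0:
            grid.per_level.append(np.zeros((0, 4)))
            continue
        cx = (np.arange(nx) + 0.5) * stride
        cy = (np.arange(ny) + 0.5) * stride
        cxg, cyg = np.meshgrid(cx, cy)  # (ny, nx)
        centers = np.stack([cxg, cyg], axis=-1).reshape(-1, 1, 2)  # (ny*nx,1,2)
        half = wh[None, :, :] / 2.0  # (1, A, 2)
        mins = centers - half
        maxs = centers + half
        level = np.concatenate([mins, maxs], axis=-1).reshape(-1, 4)
        grid.per_level.append(level)
    return grid
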