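"""Axis-aligned bounding boxes and overlap-based regression losses.

Boxes are kept in center form ``(cx, cy, w, h)`` — the convention of YOLO
label files and of the loss formulas below.  Corner-form converters are
provided for geometry that is more natural on ``(x1, y1, x2, y2)``.

Two regression losses are implemented on top of plain IoU:

* **CIoU** — ``1 - IoU + rho^2/c^2 + alpha*v`` where ``rho`` is the distance
  between box centers, ``c`` the diagonal of the smallest enclosing box,
  ``v`` an aspect-ratio consistency term and ``alpha`` its trade-off weight.
* **EIoU** — ``1 - IoU + rho^2/(wc^2 + hc^2) + (w - w')^2/wc^2 +
  (h - h')^2/hc^2`` which penalizes width and height differences directly
  instead of only their ratio, giving better-behaved gradients when the
  aspect ratio matches but the scale does not.

All functions are scalar (one pair of boxes); batch reductions belong to the
training loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "Box",
    "EPS",
    "IoUGeometry",
    "box_to_corners",
    "corners_to_box",
    "iou",
    "iou_geometry",
    "ciou_loss",
    "eiou_loss",
]

#: Small constant added to denominators so degenerate (zero-area) boxes
#: never produce a division failure.
EPS = 1e-7


@dataclass
class Box:
    """A single axis-aligned box in center form.

    Coordinates may be in pixels or normalized to ``[0, 1]``; all geometry
    here is unit-agnostic.  ``class_id`` and ``confidence`` are optional so
    the same type serves ground-truth labels and scored detections.
    """

    cx: float
    cy: float
    w: float
    h: float
    class_id: Optional[int] = None
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise ValueError(f"box width/height must be >= 0, got w={self.w}, h={self.h}")
        if self.class_id is not None and self.class_id < 0:
            raise ValueError(f"class_id must be >= 0, got {self.class_id}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def area(self) -> float:
        return self.w * self.h

    def corners(self) -> Tuple[float, float, float, float]:
        return box_to_corners(self)

    def scaled(self, s: float) -> "Box":
        """Uniformly scale all four coordinates by ``s``."""
        return Box(self.cx * s, self.cy * s, self.w * s, self.h * s,
                   self.class_id, self.confidence)


@dataclass(frozen=True)
class IoUGeometry:
    """Intermediate geometric quantities shared by the IoU-family losses."""

    iou: float
    center_dist_sq: float
    enclose_diag_sq: float
    enclose_w: float
    enclose_h: float
    v: float
    alpha: float


def box_to_corners(b: Box) -> Tuple[float, float, float, float]:
    """Center form -> ``(x1, y1, x2, y2)``."""
    hw, hh = b.w / 2.0, b.h / 2.0
    return (b.cx - hw, b.cy - hh, b.cx + hw, b.cy + hh)


def corners_to_box(x1: float, y1: float, x2: float, y2: float,
                   class_id: Optional[int] = None,
                   confidence: Optional[float] = None) -> Box:
    """``(x1, y1, x2, y2)`` -> center form.  Corners may be given in any order."""
    x1, x2 = min(x1, x2), max(x1, x2)
    y1, y2 = min(y1, y2), max(y1, y2)
    return Box((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1, class_id, confidence)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes.

    Returns 0 when the boxes are disjoint or when either box is degenerate
    (zero area).  Two zero-area boxes also give 0 by convention.
    """
    ax1, ay1, ax2, ay2 = box_to_corners(a)
    bx1, by1, bx2, by2 = box_to_corners(b)
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    if union <= 0:
        return 0.0
    return inter / union


def iou_geometry(pred: Box, gt: Box) -> IoUGeometry:
    """All geometric ingredients of the CIoU/EIoU losses for one pair."""
    ov = iou(pred, gt)
    px1, py1, px2, py2 = box_to_corners(pred)
    gx1, gy1, gx2, gy2 = box_to_corners(gt)
    wc = max(px2, gx2) - min(px1, gx1)
    hc = max(py2, gy2) - min(py1, gy1)
    c2 = wc * wc + hc * hc
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    # aspect-consistency term; EPS guards pred boxes with zero height
    v = (4.0 / math.pi ** 2) * (
        math.atan(gt.w / (gt.h + EPS)) - math.atan(pred.w / (pred.h + EPS))
    ) ** 2
    denom = (1.0 - ov) + v
    alpha = 0.0 if denom <= EPS else v / denom  # limit value at IoU=1, v=0
    return IoUGeometry(ov, rho2, c2, wc, hc, v, alpha)


def ciou_loss(pred: Box, gt: Box) -> float:
    """Complete-IoU regression loss for a single predicted/ground-truth pair."""
    if gt.w <= 0 or gt.h <= 0:
        raise ValueError("ground-truth box must have positive width and height")
    g = iou_geometry(pred, gt)
    return (1.0 - g.iou) + g.center_dist_sq / (g.enclose_diag_sq + EPS) + g.alpha * g.v


def eiou_loss(pred: Box, gt: Box) -> float:
    """Efficient-IoU loss: IoU term + center-distance term + explicit
    width and height distance terms, each normalized by the enclosing box."""
    if gt.w <= 0 or gt.h <= 0:
        raise ValueError("ground-truth box must have positive width and height")
    g = iou_geometry(pred, gt)
    wc2, hc2 = g.enclose_w ** 2, g.enclose_h ** 2
    return (
        (1.0 - g.iou)
        + g.center_dist_sq / (g.enclose_diag_sq + EPS)
        + (pred.w - gt.w) ** 2 / (wc2 + EPS)
        + (pred.h - gt.h) ** 2 / (hc2 + EPS)
    )
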