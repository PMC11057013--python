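"""Axis-aligned bounding boxes in center format.

Boxes live in continuous coordinates as (cx, cy, w, h) — the convention of
YOLO label files and of the regression-loss formulas. Corner-format
conversion helpers are provided for annotation IO and area computations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Box", "InvalidBoxError", "iou", "box_to_corners", "corners_to_box"]


class InvalidBoxError(ValueError):
    """Raised when a box has non-positive width or height."""


@dataclass(frozen=True)
class Box:
    """A single axis-aligned box, center format.

    Parameters
    ----------
    cx, cy : float
        Center coordinates (pixels or normalized units).
    w, h : float
        Width and height; must be strictly positive.
    cls : str, optional
        Class label, ``"G"`` (non-rotted pod) or ``"R"`` (rotten pod).
    conf : float, optional
        Detection confidence in [0, 1].
    """

    cx: float
    cy: float
    w: float
    h: float
    cls: Optional[str] = None
    conf: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(
                f"box width/height must be positive, got w={self.w}, h={self.h}"
            )
        if self.conf is not None and not (0.0 <= self.conf <= 1.0):
            raise InvalidBoxError(f"confidence must lie in [0,1], got {self.conf}")

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2.0

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2.0

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2.0

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2.0

    @property
    def area(self) -> float:
        return self.w * self.h

    def corners(self) -> tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


def box_to_corners(b: Box) -> tuple[float, float, float, float]:
    """(cx, cy, w, h) -> (x1, y1, x2, y2)."""
    return b.corners()


def corners_to_box(x1: float, y1: float, x2: float, y2: float, **kw) -> Box:
    """(x1, y1, x2, y2) -> center-format Box."""
    return Box(cx=(x1 + x2) / 2.0, cy=(y1 + y2) / 2.0, w=x2 - x1, h=y2 - y1, **kw)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return float(inter / union)


def iou_matrix(a_xyxy: np.ndarray, b_xyxy: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two arrays of corner-format boxes, shapes (N,4), (M,4)."""
    a = np.asarray(a_xyxy, dtype=float).reshape(-1, 4)
    b = np.asarray(b_xyxy, dtype=float).reshape(-1, 4)
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out
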