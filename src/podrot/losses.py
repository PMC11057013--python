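"""Bounding-box regression losses: IoU, CIoU, EIoU and the total-loss sum.

CIoU penalizes 1 - IoU plus a normalized center distance plus an aspect-ratio
term weighted by a piecewise trade-off alpha (zero when IoU < 0.5). EIoU
replaces the aspect-ratio surrogate with explicit width and height differences
normalized by the enclosing rectangle:

    EIoU = 1 - IoU + rho^2(b, b_gt) / c^2
               + (w - w_gt)^2 / c_w^2 + (h - h_gt)^2 / c_h^2

where c is the diagonal, c_w and c_h the width and height of the smallest
rectangle enclosing both boxes. A focal variant multiplies EIoU by IoU^gamma
so well-overlapping (high-quality) pairs dominate the gradient signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .boxes import Box, iou

__all__ = [
    "BoxRegressionTerms",
    "LossBreakdown",
    "InvalidLossError",
    "regression_terms",
    "ciou_loss",
    "eiou_loss",
    "focal_eiou_loss",
    "total_loss",
]

_EPS = 1e-9


class InvalidLossError(ValueError):
    """Raised for negative loss components or parameters."""


@dataclass(frozen=True)
class BoxRegressionTerms:
    """Intermediate geometric quantities shared by CIoU and EIoU.

    Attributes
    ----------
    iou : float
        Intersection over union.
    center_dist_sq : float
        Squared Euclidean distance rho^2 between the two box centers.
    enclosure_diag_sq : float
        Squared diagonal c^2 of the minimal enclosing rectangle.
    enclosure_w, enclosure_h : float
        Width c_w and height c_h of the minimal enclosing rectangle.
    v : float
        Aspect-ratio discrepancy term 4/pi^2 * (atan(w_gt/h_gt) - atan(w/h))^2.
    alpha : float
        Piecewise trade-off weight: 0 if IoU < 0.5, else v / (1 - IoU + v).
    """

    iou: float
    center_dist_sq: float
    enclosure_diag_sq: float
    enclosure_w: float
    enclosure_h: float
    v: float
    alpha: float


@dataclass(frozen=True)
class LossBreakdown:
    """Classification, localization and confidence loss components."""

    l_cla: float
    l_loc: float
    l_conf: float

    @property
    def total(self) -> float:
        return total_loss(self)


def _identical(pred: Box, gt: Box) -> bool:
    return (
        pred.cx == gt.cx and pred.cy == gt.cy and pred.w == gt.w and pred.h == gt.h
    )


def regression_terms(pred: Box, gt: Box) -> BoxRegressionTerms:
    """Compute all intermediate quantities of the CIoU/EIoU formulas."""
    i = iou(pred, gt)
    if _identical(pred, gt):
        # coincident boxes: every distance term vanishes exactly
        return BoxRegressionTerms(
            iou=i, center_dist_sq=0.0, enclosure_diag_sq=0.0,
            enclosure_w=gt.w, enclosure_h=gt.h, v=0.0, alpha=0.0,
        )
    rho2 = (pred.cx - gt.cx) ** 2 + (pred.cy - gt.cy) ** 2
    cw = max(pred.x2, gt.x2) - min(pred.x1, gt.x1)
    ch = max(pred.y2, gt.y2) - min(pred.y1, gt.y1)
    c2 = cw * cw + ch * ch
    v = (4.0 / math.pi**2) * (
        math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)
    ) ** 2
    alpha = 0.0 if i < 0.5 else v / (1.0 - i + v) if v > 0 else 0.0
    return BoxRegressionTerms(
        iou=i, center_dist_sq=rho2, enclosure_diag_sq=c2,
        enclosure_w=cw, enclosure_h=ch, v=v, alpha=alpha,
    )


def ciou_loss(pred: Box, gt: Box) -> float:
    """CIoU loss: 1 - IoU + rho^2/c^2 + alpha * v."""
    if _identical(pred, gt):
        return 0.0
    t = regression_terms(pred, gt)
    return (1.0 - t.iou) + t.center_dist_sq / (t.enclosure_diag_sq + _EPS) + t.alpha * t.v


def eiou_loss(pred: Box, gt: Box) -> float:
    """EIoU loss: 1 - IoU + rho^2/c^2 + (w-w_gt)^2/c_w^2 + (h-h_gt)^2/c_h^2."""
    if _identical(pred, gt):
        return 0.0
    t = regression_terms(pred, gt)
    return (
        (1.0 - t.iou)
        + t.center_dist_sq / (t.enclosure_diag_sq + _EPS)
        + (pred.w - gt.w) ** 2 / (t.enclosure_w**2 + _EPS)
        + (pred.h - gt.h) ** 2 / (t.enclosure_h**2 + _EPS)
    )


def focal_eiou_loss(pred: Box, gt: Box, gamma: float = 0.5) -> float:
    """IoU^gamma weighted EIoU; gamma = 0 recovers plain EIoU."""
    if gamma < 0:
        raise InvalidLossError(f"gamma must be nonnegative, got {gamma}")
    if gamma == 0:
        return eiou_loss(pred, gt)
    return iou(pred, gt) ** gamma * eiou_loss(pred, gt)


def total_loss(parts: LossBreakdown) -> float:
    """Sum of classification, localization and confidence components."""
    for name in ("l_cla", "l_loc", "l_conf"):
        val = getattr(parts, name)
        if val < 0:
            raise InvalidLossError(f"{name} must be nonnegative, got {val}")
    return parts.l_cla + parts.l_loc + parts.l_conf
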