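"""Evaluation statistics: greedy detection matching, precision/recall, AP and
mAP at a fixed IoU threshold, image-level Comparison Precision, and a k-fold
cross-validation harness.

Comparison Precision (CP) is an image-level accuracy: the percentage of
images on which the detector reproduces the ground truth exactly — zero
false positives and zero false negatives for both classes at the matching
IoU threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np

from .boxes import Box, iou

__all__ = [
    "MatchResult", "ImageLevelTally", "UndefinedMetricError",
    "match_detections", "precision", "recall", "average_precision", "mean_ap",
    "image_level_correct", "comparison_precision", "kfold_splits",
    "evaluate_detections", "EvalSummary",
]

CLASSES = ("G", "R")


class UndefinedMetricError(ValueError):
    pass


@dataclass
class MatchResult:
    """Per-class TP/FP/FN assignment between predictions and ground truth."""

    tp: dict
    fp: dict
    fn: dict
    pairs: list  # (class, pred index, gt index, IoU)

    def totals(self) -> tuple[int, int, int]:
        return (sum(self.tp.values()), sum(self.fp.values()), sum(self.fn.values()))


@dataclass(frozen=True)
class ImageLevelTally:
    """AS = images judged fully correct; RS = images evaluated."""

    AS: int
    RS: int

    def __post_init__(self):
        if not 0 <= self.AS <= self.RS:
            raise ValueError("tally requires 0 <= AS <= RS")


def _box_of(obj) -> Box:
    return obj.box if hasattr(obj, "box") else obj


def _cls_of(obj) -> str:
    return obj.cls


def _conf_of(obj) -> float:
    c = getattr(obj, "conf", None)
    return 1.0 if c is None else c


def match_detections(preds: Sequence, gts: Sequence, iou_thresh: float = 0.5
                     ) -> MatchResult:
    """Greedy confidence-ordered matching at an IoU threshold.

    Per class, predictions sorted by descending confidence each claim the
    highest-IoU not-yet-claimed ground truth with IoU >= threshold. Unclaimed
    predictions count as FP, unclaimed truths as FN.
    """
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError("iou_thresh must lie in (0, 1)")
    tp = {c: 0 for c in CLASSES}
    fp = {c: 0 for c in CLASSES}
    fn = {c: 0 for c in CLASSES}
    pairs = []
    for c in CLASSES:
        p_idx = [i for i, p in enumerate(preds) if _cls_of(p) == c]
        g_idx = [j for j, g in enumerate(gts) if _cls_of(g) == c]
        p_idx.sort(key=lambda i: -_conf_of(preds[i]))
        claimed: set[int] = set()
        for i in p_idx:
            best_j, best_iou = -1, iou_thresh
            for j in g_idx:
                if j in claimed:
                    continue
                v = iou(_box_of(preds[i]), _box_of(gts[j]))
                if v >= best_iou:
                    best_j, best_iou = j, v
            if best_j >= 0:
                claimed.add(best_j)
                tp[c] += 1
                pairs.append((c, i, best_j, best_iou))
            else:
                fp[c] += 1
        fn[c] = len(g_idx) - len(claimed)
    return MatchResult(tp=tp, fp=fp, fn=fn, pairs=pairs)


def precision(tp: int, fp: int) -> float:
    """100 * TP / (TP + FP)."""
    if tp + fp == 0:
        raise UndefinedMetricError("precision undefined when TP + FP = 0")
    return 100.0 * tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """100 * TP / (TP + FN)."""
    if tp + fn == 0:
        raise UndefinedMetricError("recall undefined when TP + FN = 0")
    return 100.0 * tp / (tp + fn)


def average_precision(scores: Sequence[float], is_tp: Sequence[bool],
                      n_gt: int, interpolation: str = "101point") -> float:
    """Area under the interpolated precision-recall curve for one class.

    ``scores``/``is_tp`` describe every prediction of the class over the whole
    evaluation set; ``n_gt`` is the total ground-truth count.
    """
    if n_gt <= 0:
        raise UndefinedMetricError("AP undefined with zero ground truths")
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(is_tp, dtype=bool)
    if scores.size == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    flags = flags[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    rec = tp_cum / n_gt
    prec = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # monotone precision envelope, right to left
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        # precision at recall >= r, 0 beyond max recall
        ap = 0.0
        for r in grid:
            mask = rec >= r - 1e-12
            ap += prec_env[mask][0] if mask.any() else 0.0
        return ap / 101.0
    elif interpolation == "all_point":
        r_prev = 0.0
        ap = 0.0
        for k in range(len(rec)):
            if rec[k] > r_prev:
                ap += (rec[k] - r_prev) * prec_env[k]
                r_prev = rec[k]
        return float(ap)
    raise ValueError(f"unknown interpolation {interpolation!r}")


def mean_ap(ap_per_class: Sequence[float]) -> float:
    """Arithmetic mean of per-class APs, as a percentage."""
    aps = list(ap_per_class)
    if not aps:
        raise UndefinedMetricError("mean AP of an empty AP list")
    return 100.0 * float(np.mean(aps))


def image_level_correct(preds: Sequence, gts: Sequence,
                        iou_thresh: float = 0.5) -> bool:
    """True iff matching yields zero FP and zero FN for both classes."""
    m = match_detections(preds, gts, iou_thresh)
    return sum(m.fp.values()) == 0 and sum(m.fn.values()) == 0


def comparison_precision(tally: ImageLevelTally) -> float:
    """CP = 100 * AS / RS, rounded half-up to 2 decimals."""
    if tally.RS == 0:
        raise UndefinedMetricError("CP undefined when RS = 0")
    cp = Decimal(100 * tally.AS) / Decimal(tally.RS)
    return float(cp.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def kfold_splits(n_items: int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded k-fold partition: k (train, validation) index pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_items < k:
        raise ValueError("need at least k items")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        val = folds[i]
        train = np.concatenate([folds[j] for j in range(k) if j != i])
        out.append((np.sort(train), np.sort(val)))
    return out


@dataclass
class EvalSummary:
    """Detection-set metrics pooled over a list of images."""

    precision: float
    recall: float
    ap_per_class: dict
    map: float
    cp: float
    tally: ImageLevelTally


def evaluate_detections(all_preds: Sequence[Sequence],
                        all_gts: Sequence[Sequence],
                        iou_thresh: float = 0.5) -> EvalSummary:
    """Pool matches over images and compute P, R, per-class AP, mAP and CP."""
    if len(all_preds) != len(all_gts):
        raise ValueError("prediction and ground-truth lists differ in length")
    tp = fp = fn = 0
    scores = {c: [] for c in CLASSES}
    flags = {c: [] for c in CLASSES}
    n_gt = {c: 0 for c in CLASSES}
    as_count = 0
    for preds, gts in zip(all_preds, all_gts):
        m = match_detections(preds, gts, iou_thresh)
        t, f, n = m.totals()
        tp, fp, fn = tp + t, fp + f, fn + n
        if f == 0 and n == 0:
            as_count += 1
        matched = {(c, i) for c, i, _, _ in m.pairs}
        for i, p in enumerate(preds):
            c = _cls_of(p)
            scores[c].append(_conf_of(p))
            flags[c].append((c, i) in matched)
        for g in gts:
            n_gt[_cls_of(g)] += 1
    aps = {}
    for c in CLASSES:
        if n_gt[c] > 0:
            aps[c] = average_precision(scores[c], flags[c], n_gt[c])
    tally = ImageLevelTally(AS=as_count, RS=len(all_gts))
    return EvalSummary(
        precision=precision(tp, fp) if tp + fp else 0.0,
        recall=recall(tp, fn) if tp + fn else 0.0,
        ap_per_class=aps,
        map=mean_ap(list(aps.values())) if aps else 0.0,
        cp=comparison_precision(tally),
        tally=tally,
    )
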