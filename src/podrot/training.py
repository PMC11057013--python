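"""Training loop: anchor assignment, the composite detection loss, Adam steps.

The total loss is the plain sum of three parts — classification, localization
and confidence (objectness) — with the localization term computed as EIoU by
default (CIoU selectable). Assignment follows the anchor-ratio rule: a ground
truth is matched to every anchor of a scale whose width/height ratio to the
truth is within ``anchor_t``, at the grid cell containing its center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .arch import STRIDES, ArchSpec, Detector
from .losses import LossBreakdown
from .nn.autograd import Tensor, no_grad
from .nn.layers import bce_with_logits
from .nn.optim import Adam

__all__ = ["LossConfig", "TrainConfig", "detection_loss", "train_step", "fit", "letterbox"]

_EPS = 1e-7


@dataclass
class LossConfig:
    box_loss: str = "eiou"          # "eiou" or "ciou"
    focal_gamma: float = 0.0        # IoU^gamma focal weight on the box term
    w_box: float = 0.05
    w_obj: float = 1.0
    w_cls: float = 0.5
    anchor_t: float = 4.0
    obj_balance: tuple = (4.0, 1.0, 0.4)


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    lr: float = 0.01
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)


def letterbox(img: np.ndarray, boxes_px: np.ndarray, size: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Resize an HxWx3 uint8 image to a size x size canvas, preserving aspect.

    Boxes are (M, 5) arrays of (cls, cx, cy, w, h) in source pixels; returned
    in canvas pixels.
    """
    h, w = img.shape[:2]
    r = min(size / h, size / w)
    nh, nw = int(round(h * r)), int(round(w * r))
    yi = (np.arange(nh) / r).astype(int).clip(0, h - 1)
    xi = (np.arange(nw) / r).astype(int).clip(0, w - 1)
    resized = img[yi][:, xi]
    canvas = np.full((size, size, 3), 114, dtype=img.dtype)
    top, left = (size - nh) // 2, (size - nw) // 2
    canvas[top : top + nh, left : left + nw] = resized
    out = boxes_px.astype(np.float64).copy().reshape(-1, 5)
    if len(out):
        out[:, 1] = out[:, 1] * r + left
        out[:, 2] = out[:, 2] * r + top
        out[:, 3] *= r
        out[:, 4] *= r
    return canvas, out


def images_to_batch(imgs: list[np.ndarray]) -> np.ndarray:
    """Stack HxWx3 uint8 images into an (N,3,H,W) float32 batch in [0,1]."""
    arr = np.stack(imgs).astype(np.float32) / 255.0
    return arr.transpose(0, 3, 1, 2)


def build_targets(spec: ArchSpec, targets: np.ndarray, cfg: LossConfig):
    """Assign ground truths to (scale, anchor, cell) slots.

    ``targets``: (M, 6) rows of (img_idx, cls, cx, cy, w, h) in input pixels.
    Returns, per scale: index arrays (b, a, gj, gi), target boxes (cx, cy, w,
    h in pixels), matched anchor wh, and class ids.
    """
    per_scale = []
    for si, stride in enumerate(STRIDES):
        anchors = np.asarray(spec.anchors[si], dtype=np.float32)
        ng = spec.input_size // stride
        if targets.size == 0:
            per_scale.append(None)
            continue
        wh = targets[:, 4:6]
        r = wh[:, None, :] / anchors[None, :, :]
        keep = np.maximum(r, 1.0 / r).max(axis=2) < cfg.anchor_t  # (M, na)
        mi, ai = np.nonzero(keep)
        if mi.size == 0:
            per_scale.append(None)
            continue
        t = targets[mi]
        gi = np.clip((t[:, 2] / stride).astype(int), 0, ng - 1)
        gj = np.clip((t[:, 3] / stride).astype(int), 0, ng - 1)
        per_scale.append({
            "b": t[:, 0].astype(int), "a": ai, "gj": gj, "gi": gi,
            "tbox": t[:, 2:6].astype(np.float32),
            "anchor": anchors[ai], "cls": t[:, 1].astype(int),
        })
    return per_scale


def _pairwise_box_terms(pb: dict, tb: np.ndarray):
    """Differentiable IoU / enclosure terms between predicted and target boxes.

    ``pb``: dict of Tensors cx, cy, w, h; ``tb``: (M,4) constant array.
    """
    tcx, tcy, tw, th = (Tensor(tb[:, i]) for i in range(4))
    px1, px2 = pb["cx"] - pb["w"] * 0.5, pb["cx"] + pb["w"] * 0.5
    py1, py2 = pb["cy"] - pb["h"] * 0.5, pb["cy"] + pb["h"] * 0.5
    tx1, tx2 = tcx - tw * 0.5, tcx + tw * 0.5
    ty1, ty2 = tcy - th * 0.5, tcy + th * 0.5
    iw = (px2.minimum(tx2) - px1.maximum(tx1)).clamp_min(0.0)
    ih = (py2.minimum(ty2) - py1.maximum(ty1)).clamp_min(0.0)
    inter = iw * ih
    union = pb["w"] * pb["h"] + tw * th - inter
    iou = inter / (union + _EPS)
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    rho2 = (pb["cx"] - tcx) ** 2 + (pb["cy"] - tcy) ** 2
    return iou, cw, ch, rho2, (tw, th)


def box_regression_loss(pb: dict, tb: np.ndarray, cfg: LossConfig):
    """Per-pair EIoU/CIoU loss tensor plus detached IoU (for objness targets)."""
    iou, cw, ch, rho2, (tw, th) = _pairwise_box_terms(pb, tb)
    c2 = cw**2 + ch**2
    if cfg.box_loss == "eiou":
        loss = (
            1.0 - iou + rho2 / (c2 + _EPS)
            + (pb["w"] - tw) ** 2 / (cw**2 + _EPS)
            + (pb["h"] - th) ** 2 / (ch**2 + _EPS)
        )
        if cfg.focal_gamma > 0:
            loss = loss * Tensor(iou.data ** cfg.focal_gamma)
    elif cfg.box_loss == "ciou":
        v = (4.0 / math.pi**2) * ((tw / th).atan() - (pb["w"] / pb["h"]).atan()) ** 2
        # alpha: piecewise weight, treated as a constant during backprop
        alpha = np.where(
            iou.data < 0.5, 0.0, v.data / (1.0 - iou.data + v.data + _EPS)
        ).astype(np.float32)
        loss = 1.0 - iou + rho2 / (c2 + _EPS) + Tensor(alpha) * v
    else:
        raise ValueError(f"unknown box loss {cfg.box_loss!r}")
    return loss, iou.data


def detection_loss(raws: list, spec: ArchSpec, targets: np.ndarray,
                   cfg: LossConfig) -> tuple[Tensor, LossBreakdown]:
    """Composite loss over a batch. Returns (scalar tensor, detached parts)."""
    nc = spec.num_classes
    na = len(spec.anchors[0])
    assigned = build_targets(spec, targets, cfg)
    l_box = Tensor(0.0)
    l_cls = Tensor(0.0)
    l_obj = Tensor(0.0)
    n_assigned = 0
    for si, (raw, stride) in enumerate(zip(raws, STRIDES)):
        n, _, h, w = raw.shape
        p = raw.reshape(n, na, 5 + nc, h, w).transpose(0, 1, 3, 4, 2)
        obj_t = np.zeros((n, na, h, w, 1), dtype=np.float32)
        a = assigned[si]
        if a is not None:
            idx = (a["b"], a["a"], a["gj"], a["gi"])
            ps = p[idx]  # (M, 5+nc)
            gxy = np.stack([a["gi"], a["gj"]], axis=1).astype(np.float32)
            pxy = (ps[:, 0:2].sigmoid() * 2.0 - 0.5 + Tensor(gxy)) * float(stride)
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * Tensor(a["anchor"])
            pb = {"cx": pxy[:, 0], "cy": pxy[:, 1], "w": pwh[:, 0], "h": pwh[:, 1]}
            pair_loss, iou_det = box_regression_loss(pb, a["tbox"], cfg)
            l_box = l_box + pair_loss.mean()
            n_assigned += len(a["b"])
            cls_t = np.zeros((len(a["cls"]), nc), dtype=np.float32)
            cls_t[np.arange(len(a["cls"])), a["cls"]] = 1.0
            l_cls = l_cls + bce_with_logits(ps[:, 5:], cls_t)
            obj_t[idx[0], idx[1], idx[2], idx[3], 0] = np.clip(iou_det, 0.0, 1.0)
        l_obj = l_obj + bce_with_logits(p[..., 4:5], obj_t) * cfg.obj_balance[si]
    total = cfg.w_box * l_box + cfg.w_obj * l_obj + cfg.w_cls * l_cls
    parts = LossBreakdown(
        l_cla=float(cfg.w_cls * l_cls.data),
        l_loc=float(cfg.w_box * l_box.data),
        l_conf=float(cfg.w_obj * l_obj.data),
    )
    return total, parts


def train_step(detector: Detector, batch: tuple[np.ndarray, np.ndarray],
               optimizer: Adam, cfg: LossConfig) -> LossBreakdown:
    """One optimizer update on a batch of (images (N,3,S,S), targets (M,6))."""
    images, targets = batch
    if len(images) == 0:
        raise ValueError("empty batch")
    detector.set_training(True)
    raws = detector(Tensor(images))
    total, parts = detection_loss(raws, detector.spec, targets, cfg)
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return parts


def fit(detector: Detector, images: list[np.ndarray], labels: list[np.ndarray],
        cfg: TrainConfig, verbose: bool = False) -> list[float]:
    """Mini-batch training over letterboxed images; returns per-epoch losses.

    ``labels[i]``: (M_i, 5) rows of (cls, cx, cy, w, h) in source pixels.
    """
    size = detector.spec.input_size
    lb = [letterbox(im, lab, size) for im, lab in zip(images, labels)]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(detector.parameters(), lr=cfg.lr)
    history = []
    n = len(lb)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        nb = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            imgs = images_to_batch([lb[i][0] for i in idx])
            tgts = []
            for bi, i in enumerate(idx):
                lab = lb[i][1]
                for row in lab:
                    tgts.append([bi, row[0], row[1], row[2], row[3], row[4]])
            tgts = np.asarray(tgts, dtype=np.float32).reshape(-1, 6)
            parts = train_step(detector, (imgs, tgts), opt, cfg.loss)
            epoch_loss += parts.total
            nb += 1
        history.append(epoch_loss / max(nb, 1))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: loss {history[-1]:.4f}")
    return history
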