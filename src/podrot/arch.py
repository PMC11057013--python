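"""Detector assembly: CSP backbone + FPN/PAN neck + three-scale head.

An :class:`ArchSpec` is an ordered list of stage descriptors (conv, C3, SPPF,
SA, upsample, concat, head) with resolved channel widths. The small variant
follows the stock small-detector layout (four backbone C3 stages, SPPF,
top-down + bottom-up fusion, strides 8/16/32). ``insert_sa_after_c3`` derives
the attention-enhanced variant by placing one shuffle-attention block after
every backbone C3 stage; ``build_detector`` materializes weights.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .boxes import Box, iou_matrix
from .nn.autograd import Tensor, concat, no_grad
from .nn.layers import C3, SPPF, ConvBNSiLU, Module, SALayer, Upsample

__all__ = [
    "ArchSpec", "ArchSpecError", "Detection", "small_arch", "tiny_arch",
    "insert_sa_after_c3", "build_detector", "Detector", "decode_outputs",
    "decode_and_nms", "nms", "sa_insertion_param_delta",
]

CLASS_NAMES = ("G", "R")

# stock anchors (pixels, per stride-8/16/32 scale)
DEFAULT_ANCHORS = [
    [[10, 13], [16, 30], [33, 23]],
    [[30, 61], [62, 45], [59, 119]],
    [[116, 90], [156, 198], [373, 326]],
]
STRIDES = (8, 16, 32)


class ArchSpecError(ValueError):
    pass


@dataclass(frozen=True)
class Detection:
    """One decoded, NMS-surviving detection."""

    box: Box
    cls: str
    conf: float


@dataclass
class ArchSpec:
    """Ordered stage descriptors plus global settings.

    Each stage is a dict with keys ``kind`` (conv/C3/SPPF/SA/upsample/concat/
    head), ``from`` (absolute stage index, list of indices, or -1 for the
    previous stage), ``c`` (output channels), and kind-specific keys
    (``k``, ``s``, ``n``, ``shortcut``, ``groups``, ``section``).
    """

    input_size: int = 640
    num_classes: int = 2
    anchors: list = field(default_factory=lambda: copy.deepcopy(DEFAULT_ANCHORS))
    sa_groups: int = 16
    stages: list = field(default_factory=list)

    def backbone_c3_indices(self) -> list[int]:
        return [
            i for i, s in enumerate(self.stages)
            if s["kind"] == "C3" and s.get("section") == "backbone"
        ]

    def has_sa(self) -> bool:
        return any(s["kind"] == "SA" for s in self.stages)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "input_size": self.input_size,
                "num_classes": self.num_classes,
                "anchors": self.anchors,
                "sa_groups": self.sa_groups,
                "stages": self.stages,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ArchSpec":
        d = yaml.safe_load(text)
        return cls(**d)


def _make_div(x: float, div: int = 8) -> int:
    return max(div, int(round(x / div) * div))


def small_arch(width_mult: float = 0.5, depth_mult: float = 0.33,
               input_size: int = 640, num_classes: int = 2,
               sa_groups: int = 16) -> ArchSpec:
    """The small-variant layout: 4 backbone C3 stages, SPPF, FPN/PAN neck."""

    def cw(c):  # scaled channel width
        return _make_div(c * width_mult)

    def dn(n):  # scaled repeat count
        return max(1, round(n * depth_mult))

    B, N = "backbone", "neck"
    stages = [
        {"kind": "conv", "from": -1, "c": cw(64), "k": 6, "s": 2, "section": B},     # 0 P1/2
        {"kind": "conv", "from": -1, "c": cw(128), "k": 3, "s": 2, "section": B},    # 1 P2/4
        {"kind": "C3", "from": -1, "c": cw(128), "n": dn(3), "shortcut": True, "section": B},   # 2
        {"kind": "conv", "from": -1, "c": cw(256), "k": 3, "s": 2, "section": B},    # 3 P3/8
        {"kind": "C3", "from": -1, "c": cw(256), "n": dn(6), "shortcut": True, "section": B},   # 4
        {"kind": "conv", "from": -1, "c": cw(512), "k": 3, "s": 2, "section": B},    # 5 P4/16
        {"kind": "C3", "from": -1, "c": cw(512), "n": dn(9), "shortcut": True, "section": B},   # 6
        {"kind": "conv", "from": -1, "c": cw(1024), "k": 3, "s": 2, "section": B},   # 7 P5/32
        {"kind": "C3", "from": -1, "c": cw(1024), "n": dn(3), "shortcut": True, "section": B},  # 8
        {"kind": "SPPF", "from": -1, "c": cw(1024), "k": 5, "section": B},           # 9
        {"kind": "conv", "from": -1, "c": cw(512), "k": 1, "s": 1, "section": N},    # 10
        {"kind": "upsample", "from": -1, "section": N},                              # 11
        {"kind": "concat", "from": [-1, 6], "section": N},                           # 12
        {"kind": "C3", "from": -1, "c": cw(512), "n": dn(3), "shortcut": False, "section": N},  # 13
        {"kind": "conv", "from": -1, "c": cw(256), "k": 1, "s": 1, "section": N},    # 14
        {"kind": "upsample", "from": -1, "section": N},                              # 15
        {"kind": "concat", "from": [-1, 4], "section": N},                           # 16
        {"kind": "C3", "from": -1, "c": cw(256), "n": dn(3), "shortcut": False, "section": N},  # 17 P3
        {"kind": "conv", "from": -1, "c": cw(256), "k": 3, "s": 2, "section": N},    # 18
        {"kind": "concat", "from": [-1, 14], "section": N},                          # 19
        {"kind": "C3", "from": -1, "c": cw(512), "n": dn(3), "shortcut": False, "section": N},  # 20 P4
        {"kind": "conv", "from": -1, "c": cw(512), "k": 3, "s": 2, "section": N},    # 21
        {"kind": "concat", "from": [-1, 10], "section": N},                          # 22
        {"kind": "C3", "from": -1, "c": cw(1024), "n": dn(3), "shortcut": False, "section": N}, # 23 P5
        {"kind": "head", "from": [17, 20, 23], "section": "head"},                   # 24
    ]
    return ArchSpec(
        input_size=input_size, num_classes=num_classes,
        sa_groups=sa_groups, stages=stages,
    )


def tiny_arch(input_size: int = 160, num_classes: int = 2) -> ArchSpec:
    """A CPU-scale variant for smoke training: width 1/8, depth 1, SA groups 4."""
    return small_arch(
        width_mult=0.125, depth_mult=0.12, input_size=input_size,
        num_classes=num_classes, sa_groups=4,
    )


def insert_sa_after_c3(base: ArchSpec, groups: Optional[int] = None) -> ArchSpec:
    """Place one SA block after each backbone C3 stage; neck C3 untouched."""
    c3_idx = base.backbone_c3_indices()
    if not c3_idx:
        raise ArchSpecError("architecture has no backbone C3 stage")
    if any(s["kind"] == "SA" for s in base.stages):
        raise ArchSpecError("SA blocks already present; refusing double insertion")
    groups = groups if groups is not None else base.sa_groups
    insert_after = set(c3_idx)
    new_stages: list = []
    old_to_new: dict[int, int] = {}
    for i, st in enumerate(base.stages):
        old_to_new[i] = len(new_stages)
        new_stages.append(copy.deepcopy(st))
        if i in insert_after:
            new_stages.append({
                "kind": "SA", "from": -1, "c": st["c"],
                "groups": groups, "section": "backbone",
            })
    # SA output replaces the C3 output for downstream consumers
    for i in insert_after:
        old_to_new[i] = old_to_new[i] + 1
    out_stages = []
    for i, st in enumerate(new_stages):
        st = dict(st)
        frm = st["from"]
        if isinstance(frm, list):
            st["from"] = [f if f == -1 else old_to_new[f] for f in frm]
        elif frm != -1:
            st["from"] = old_to_new[frm]
        out_stages.append(st)
    return ArchSpec(
        input_size=base.input_size, num_classes=base.num_classes,
        anchors=copy.deepcopy(base.anchors), sa_groups=groups, stages=out_stages,
    )


def sa_insertion_param_delta(base: ArchSpec) -> int:
    """Analytic parameter count added by SA insertion: 2C per backbone C3."""
    return sum(2 * base.stages[i]["c"] for i in base.backbone_c3_indices())


class _Head(Module):
    """Coupled prediction head: one 1x1 conv per scale, (5+nc)*na channels."""

    def __init__(self, cins: list[int], num_classes: int, na: int,
                 rng: np.random.Generator):
        self.num_classes = num_classes
        self.na = na
        no = na * (5 + num_classes)
        self.convs = []
        self.biases = []
        for cin in cins:
            w = rng.normal(0, np.sqrt(2.0 / cin), size=(no, cin, 1, 1)).astype(np.float32)
            b = np.zeros(no, dtype=np.float32)
            # bias the objectness logits low so an untrained net is quiet
            b.reshape(na, 5 + num_classes)[:, 4] = -5.0
            self.convs.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(b, requires_grad=True))

    def forward(self, xs: list[Tensor]) -> list[Tensor]:
        return [
            x.conv2d(w, b, stride=1, padding=0)
            for x, w, b in zip(xs, self.convs, self.biases)
        ]


class Detector(Module):
    """Forward-callable detector built from an :class:`ArchSpec`."""

    def __init__(self, spec: ArchSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers: list = []
        self.froms: list = []
        channels: list[int] = []
        cin = 3
        for st in spec.stages:
            kind = st["kind"]
            frm = st["from"]
            if kind == "head":
                cins = [channels[f] for f in frm]
                layer = _Head(cins, spec.num_classes, len(spec.anchors[0]), rng)
                cout = 0
            else:
                src = cin if frm == -1 else (
                    sum(channels[f] if f != -1 else cin for f in frm)
                    if isinstance(frm, list) else channels[frm]
                )
                if kind == "conv":
                    layer = ConvBNSiLU(src, st["c"], st["k"], st["s"], rng)
                    cout = st["c"]
                elif kind == "C3":
                    layer = C3(src, st["c"], st["n"], st["shortcut"], rng)
                    cout = st["c"]
                elif kind == "SPPF":
                    layer = SPPF(src, st["c"], st["k"], rng)
                    cout = st["c"]
                elif kind == "SA":
                    layer = SALayer(st["c"], st.get("groups", spec.sa_groups))
                    cout = st["c"]
                elif kind == "upsample":
                    layer = Upsample()
                    cout = src
                elif kind == "concat":
                    layer = None
                    cout = src
                else:
                    raise ArchSpecError(f"unknown stage kind {kind!r}")
            self.layers.append(layer)
            self.froms.append(frm)
            channels.append(cout)
            cin = cout

    def forward(self, x: Tensor) -> list[Tensor]:
        outputs: list = []
        prev = x
        result = None
        for layer, frm, st in zip(self.layers, self.froms, self.spec.stages):
            if st["kind"] == "concat":
                srcs = [prev if f == -1 else outputs[f] for f in frm]
                y = concat(srcs, axis=1)
            elif st["kind"] == "head":
                y = layer([outputs[f] for f in frm])
                result = y
            else:
                src = prev if frm == -1 else outputs[frm]
                y = layer(src)
            outputs.append(y)
            prev = y
        return result

    # -- checkpointing --------------------------------------------------------

    def save(self, path) -> None:
        state = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Module):
                sub: dict = {}
                layer._state(sub, f"{i}.")
                state.update(sub)
        np.savez(path, spec=self.spec.to_yaml(), **state)

    @classmethod
    def load(cls, path) -> "Detector":
        with np.load(path, allow_pickle=False) as z:
            spec = ArchSpec.from_yaml(str(z["spec"]))
            det = cls(spec)
            for i, layer in enumerate(det.layers):
                if isinstance(layer, Module):
                    sub = {
                        k[len(f"{i}."):]: z[k]
                        for k in z.files if k.startswith(f"{i}.")
                    }
                    layer.load_state_arrays(sub)
        return det


def build_detector(spec: ArchSpec, seed: int = 0) -> Detector:
    return Detector(spec, seed=seed)


def decode_outputs(raws: list, spec: ArchSpec) -> np.ndarray:
    """Decode raw head maps into (N, total_anchors, 5+nc) sigmoid-space arrays.

    Boxes come out in pixel center format: xy = (2*sig-0.5 + grid) * stride,
    wh = (2*sig)^2 * anchor.
    """
    nc = spec.num_classes
    na = len(spec.anchors[0])
    decoded = []
    for raw, anchors, stride in zip(raws, spec.anchors, STRIDES):
        data = raw.data if isinstance(raw, Tensor) else raw
        n, _, h, w = data.shape
        p = data.reshape(n, na, 5 + nc, h, w).transpose(0, 1, 3, 4, 2)
        s = 1.0 / (1.0 + np.exp(-p))
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        anc = np.asarray(anchors, dtype=np.float32)  # (na, 2)
        xy = (2.0 * s[..., :2] - 0.5 + np.stack([gx, gy], axis=-1)) * stride
        wh = (2.0 * s[..., 2:4]) ** 2 * anc[None, :, None, None, :]
        obj = s[..., 4:5]
        cls = s[..., 5:]
        out = np.concatenate([xy, wh, obj, cls], axis=-1)
        decoded.append(out.reshape(n, na * h * w, 5 + nc))
    return np.concatenate(decoded, axis=1)


def nms(xyxy: np.ndarray, scores: np.ndarray, iou_thresh: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores)
    keep: list[int] = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        ious = iou_matrix(xyxy[i], xyxy[order[1:]])[0]
        order = order[1:][ious <= iou_thresh]
    return keep


def decode_and_nms(raws: list, spec: ArchSpec, conf_thresh: float = 0.25,
                   iou_thresh: float = 0.45, max_det: int = 300) -> list[list[Detection]]:
    """Full postprocessing: decode, confidence filter, per-class NMS."""
    if not (0.0 <= conf_thresh <= 1.0 and 0.0 <= iou_thresh <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    batch = decode_outputs(raws, spec)
    results: list[list[Detection]] = []
    for pred in batch:
        obj = pred[:, 4]
        cls_prob = pred[:, 5:] * obj[:, None]
        cls_id = cls_prob.argmax(axis=1)
        conf = cls_prob[np.arange(len(pred)), cls_id]
        m = conf >= conf_thresh
        dets: list[Detection] = []
        if m.any():
            boxes = pred[m, :4]
            conf_m, cls_m = conf[m], cls_id[m]
            xyxy = np.stack([
                boxes[:, 0] - boxes[:, 2] / 2, boxes[:, 1] - boxes[:, 3] / 2,
                boxes[:, 0] + boxes[:, 2] / 2, boxes[:, 1] + boxes[:, 3] / 2,
            ], axis=1)
            for c in np.unique(cls_m):
                idx = np.where(cls_m == c)[0]
                kept = nms(xyxy[idx], conf_m[idx], iou_thresh)
                for j in (idx[k] for k in kept):
                    b = boxes[j]
                    if b[2] <= 0 or b[3] <= 0:
                        continue
                    dets.append(Detection(
                        box=Box(float(b[0]), float(b[1]), float(b[2]), float(b[3]),
                                cls=CLASS_NAMES[int(c)], conf=float(min(conf_m[j], 1.0))),
                        cls=CLASS_NAMES[int(c)], conf=float(min(conf_m[j], 1.0)),
                    ))
        dets.sort(key=lambda d: -d.conf)
        results.append(dets[:max_det])
    return results
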