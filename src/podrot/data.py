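"""Annotation IO and the dataset pipeline: VOC XML, YOLO txt, resize,
augmentation primitives, train/test split and label census.

Class names are ``G`` (non-rotted pod) and ``R`` (rotten pod); YOLO class
indices are 0 and 1 respectively. VOC corner coordinates are treated as
1-based inclusive pixel corners; YOLO labels are normalized center format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from scipy import ndimage

from .boxes import Box, corners_to_box

__all__ = [
    "AnnotatedImage", "LabelCensus", "UnknownClassError", "CLASSES",
    "read_voc_xml", "write_voc_xml", "write_yolo_txt", "read_yolo_txt",
    "resize_with_boxes", "augment", "random_combo", "split_dataset", "census",
    "AUGMENT_OPS",
]

CLASSES = ("G", "R")
CLASS_TO_INDEX = {"G": 0, "R": 1}

AUGMENT_OPS = ("noise", "cutout", "rotation", "cropping", "translation", "hflip", "vflip")

# canonical application order for combined augmentations
_OP_ORDER = {op: i for i, op in enumerate(AUGMENT_OPS)}


class UnknownClassError(ValueError):
    pass


@dataclass
class AnnotatedImage:
    """An RGB raster with its center-format, class-labeled boxes."""

    image: np.ndarray  # (H, W, 3) uint8
    boxes: list[Box] = field(default_factory=list)
    source_id: str = ""

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


@dataclass(frozen=True)
class LabelCensus:
    n_G: int
    n_R: int

    @property
    def total(self) -> int:
        return self.n_G + self.n_R

    def __add__(self, other: "LabelCensus") -> "LabelCensus":
        return LabelCensus(self.n_G + other.n_G, self.n_R + other.n_R)


# ---------------------------------------------------------------------------
# formats
# ---------------------------------------------------------------------------

def read_voc_xml(path) -> tuple[str, tuple[int, int], list[Box]]:
    """Parse a Pascal VOC annotation file.

    Returns (source id, (width, height), boxes) with boxes converted from
    1-based inclusive corners to continuous center format.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    fname = root.findtext("filename") or Path(path).stem
    w = int(root.findtext("size/width"))
    h = int(root.findtext("size/height"))
    boxes = []
    for obj in root.findall("object"):
        name = obj.findtext("name")
        if name not in CLASSES:
            raise UnknownClassError(
                f"unknown object class {name!r} in {path}; expected one of {CLASSES}"
            )
        xmin = float(obj.findtext("bndbox/xmin"))
        ymin = float(obj.findtext("bndbox/ymin"))
        xmax = float(obj.findtext("bndbox/xmax"))
        ymax = float(obj.findtext("bndbox/ymax"))
        boxes.append(corners_to_box(xmin, ymin, xmax, ymax, cls=name))
    return fname, (w, h), boxes


def write_voc_xml(ann: AnnotatedImage, path) -> None:
    """Write a Pascal VOC annotation for an annotated image."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = ann.source_id
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    for b in ann.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.cls
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = f"{b.x1:.2f}"
        etree.SubElement(bb, "ymin").text = f"{b.y1:.2f}"
        etree.SubElement(bb, "xmax").text = f"{b.x2:.2f}"
        etree.SubElement(bb, "ymax").text = f"{b.y2:.2f}"
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def write_yolo_txt(ann: AnnotatedImage, path) -> None:
    """One line per box: ``cls cx cy w h`` normalized to [0, 1], 6 decimals."""
    lines = []
    w, h = ann.width, ann.height
    for b in ann.boxes:
        cx, cy = b.cx / w, b.cy / h
        bw, bh = b.w / w, b.h / h
        cx, cy = min(max(cx, 0.0), 1.0), min(max(cy, 0.0), 1.0)
        bw, bh = min(bw, 1.0), min(bh, 1.0)
        lines.append(f"{CLASS_TO_INDEX[b.cls]} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path, image_w: int, image_h: int) -> list[Box]:
    """Parse normalized YOLO labels back into pixel-space center boxes."""
    boxes = []
    text = Path(path).read_text()
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        ci = int(parts[0])
        cx, cy, w, h = (float(p) for p in parts[1:5])
        conf = float(parts[5]) if len(parts) > 5 else None
        boxes.append(Box(cx * image_w, cy * image_h, w * image_w, h * image_h,
                         cls=CLASSES[ci], conf=conf))
    return boxes


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def resize_with_boxes(ann: AnnotatedImage, target_w: int, target_h: int) -> AnnotatedImage:
    """Scale image and boxes by (target_w / w, target_h / h)."""
    if target_w <= 0 or target_h <= 0:
        raise ValueError("target dimensions must be positive")
    h, w = ann.image.shape[:2]
    if (w, h) == (target_w, target_h):
        return AnnotatedImage(ann.image.copy(), list(ann.boxes), ann.source_id)
    sx, sy = target_w / w, target_h / h
    yi = np.clip((np.arange(target_h) / sy).astype(int), 0, h - 1)
    xi = np.clip((np.arange(target_w) / sx).astype(int), 0, w - 1)
    img = ann.image[yi][:, xi]
    boxes = [replace(b, cx=b.cx * sx, cy=b.cy * sy, w=b.w * sx, h=b.h * sy)
             for b in ann.boxes]
    return AnnotatedImage(img, boxes, ann.source_id)


def _clip_box(b: Box, w: int, h: int, min_keep: float) -> Box | None:
    """Clip a box to image bounds; drop it if < min_keep of its area remains."""
    x1, y1 = max(b.x1, 0.0), max(b.y1, 0.0)
    x2, y2 = min(b.x2, float(w)), min(b.y2, float(h))
    if x2 - x1 <= 1.0 or y2 - y1 <= 1.0:
        return None
    kept = (x2 - x1) * (y2 - y1)
    if kept / b.area < min_keep:
        return None
    return corners_to_box(x1, y1, x2, y2, cls=b.cls, conf=b.conf)


def augment(ann: AnnotatedImage, ops: Sequence[str], seed: int,
            min_keep: float = 0.25) -> AnnotatedImage:
    """Apply augmentation primitives in canonical order, seeded.

    Boxes are transformed consistently with pixels; boxes retaining less than
    ``min_keep`` of their area after cropping/cutout/translation are dropped.
    """
    if not ops:
        raise ValueError("ops must be non-empty")
    unknown = set(ops) - set(AUGMENT_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    img = ann.image.copy()
    boxes = list(ann.boxes)
    for op in sorted(set(ops), key=_OP_ORDER.get):
        h, w = img.shape[:2]
        if op == "noise":
            sigma = rng.uniform(5.0, 15.0)
            noisy = img.astype(np.float32) + rng.normal(0, sigma, img.shape)
            img = np.clip(noisy, 0, 255).astype(np.uint8)
        elif op == "cutout":
            n_sq = rng.integers(1, 4)
            side = max(2, int(0.10 * w))
            for _ in range(n_sq):
                cx = rng.integers(0, w)
                cy = rng.integers(0, h)
                x1, x2 = max(cx - side // 2, 0), min(cx + side // 2, w)
                y1, y2 = max(cy - side // 2, 0), min(cy + side // 2, h)
                img[y1:y2, x1:x2] = 0
                kept = []
                for b in boxes:
                    ox = max(0.0, min(b.x2, x2) - max(b.x1, x1))
                    oy = max(0.0, min(b.y2, y2) - max(b.y1, y1))
                    if 1.0 - (ox * oy) / b.area >= min_keep:
                        kept.append(b)
                boxes = kept
        elif op == "rotation":
            angle = rng.uniform(-15.0, 15.0)
            img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant")
            theta = math.radians(-angle)  # image-coordinate rotation (y down)
            c0x, c0y = w / 2.0, h / 2.0
            cos_t, sin_t = math.cos(theta), math.sin(theta)
            new_boxes = []
            for b in boxes:
                xs = np.array([b.x1, b.x2, b.x2, b.x1]) - c0x
                ys = np.array([b.y1, b.y1, b.y2, b.y2]) - c0y
                xr = xs * cos_t - ys * sin_t + c0x
                yr = xs * sin_t + ys * cos_t + c0y
                nb = corners_to_box(xr.min(), yr.min(), xr.max(), yr.max(),
                                    cls=b.cls, conf=b.conf)
                nb = _clip_box(nb, w, h, min_keep)
                if nb is not None:
                    new_boxes.append(nb)
            boxes = new_boxes
        elif op == "cropping":
            fx = rng.uniform(0.7, 0.95)
            fy = rng.uniform(0.7, 0.95)
            cw, ch = int(w * fx), int(h * fy)
            x0 = rng.integers(0, w - cw + 1)
            y0 = rng.integers(0, h - ch + 1)
            img = img[y0 : y0 + ch, x0 : x0 + cw]
            new_boxes = []
            for b in boxes:
                nb = Box(b.cx - x0, b.cy - y0, b.w, b.h, cls=b.cls, conf=b.conf)
                nb = _clip_box(nb, cw, ch, min_keep)
                if nb is not None:
                    new_boxes.append(nb)
            boxes = new_boxes
        elif op == "translation":
            dx = int(rng.integers(-w // 5, w // 5 + 1))
            dy = int(rng.integers(-h // 5, h // 5 + 1))
            shifted = np.zeros_like(img)
            src_x = slice(max(0, -dx), min(w, w - dx))
            src_y = slice(max(0, -dy), min(h, h - dy))
            dst_x = slice(max(0, dx), min(w, w + dx))
            dst_y = slice(max(0, dy), min(h, h + dy))
            shifted[dst_y, dst_x] = img[src_y, src_x]
            img = shifted
            new_boxes = []
            for b in boxes:
                nb = Box(b.cx + dx, b.cy + dy, b.w, b.h, cls=b.cls, conf=b.conf)
                nb = _clip_box(nb, w, h, min_keep)
                if nb is not None:
                    new_boxes.append(nb)
            boxes = new_boxes
        elif op == "hflip":
            img = img[:, ::-1].copy()
            boxes = [replace(b, cx=w - b.cx) for b in boxes]
        elif op == "vflip":
            img = img[::-1].copy()
            boxes = [replace(b, cy=h - b.cy) for b in boxes]
    return AnnotatedImage(img, boxes, ann.source_id)


def random_combo(ann: AnnotatedImage, n_ops: int, seed: int) -> AnnotatedImage:
    """Sample ``n_ops`` distinct primitives uniformly and apply them in order."""
    if n_ops > len(AUGMENT_OPS):
        raise ValueError(f"n_ops must be <= {len(AUGMENT_OPS)}")
    if n_ops == 0:
        return AnnotatedImage(ann.image.copy(), list(ann.boxes), ann.source_id)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(AUGMENT_OPS), size=n_ops, replace=False)
    ops = [AUGMENT_OPS[i] for i in sorted(chosen)]
    return augment(ann, ops, seed=seed + 1)


def sample_combo_ops(n_ops: int, seed: int) -> tuple[str, ...]:
    """The op subset :func:`random_combo` would apply for this seed."""
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(AUGMENT_OPS), size=n_ops, replace=False)
    return tuple(AUGMENT_OPS[i] for i in sorted(chosen))


# ---------------------------------------------------------------------------
# dataset bookkeeping
# ---------------------------------------------------------------------------

def split_dataset(items: Sequence, ratio: float, seed: int) -> tuple[list, list]:
    """Seeded shuffle then partition into round(n * ratio) / remainder."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    n_train = int(round(len(items) * ratio))
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train:]]
    return train, test


def census(annotations: Iterable) -> LabelCensus:
    """Count G and R labels over annotated images or box lists."""
    n_g = n_r = 0
    for ann in annotations:
        boxes = ann.boxes if isinstance(ann, AnnotatedImage) else ann
        for b in boxes:
            if b.cls == "G":
                n_g += 1
            elif b.cls == "R":
                n_r += 1
            else:
                raise UnknownClassError(f"unknown class {b.cls!r}")
    return LabelCensus(n_g, n_r)
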