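"""Synthetic pod-rot scenes with exact ground truth.

Each scene is a soil-toned canvas with elliptical "pods" of two visual
classes — non-rotted (tan, light speckle) and rotten (dark brown, black
mottle) — plus curvilinear root/stem distractor strokes that deliberately
share the rotten palette. Pods are placed under one of three adhesion
strata describing pairwise bounding-box overlap:

* ``none``   — all pairwise box IoUs are exactly 0;
* ``slight`` — at least one pair with IoU in (0, 0.3], none above 0.3;
* ``severe`` — at least one pair with IoU above 0.3.

Ground-truth boxes are the tight axis-aligned bounds of each drawn ellipse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .boxes import Box, iou
from .data import AnnotatedImage, write_voc_xml, write_yolo_txt
from .grading import DEFAULT_SCALE, GradeRecord, GradeScale, record_from_detections

__all__ = [
    "SceneSpec", "PlacementError", "ADHESION_LEVELS",
    "generate_scene", "generate_validation_set", "ground_truth_grading",
    "write_scene_dataset",
]

ADHESION_LEVELS = ("none", "slight", "severe")
SLIGHT_MAX_IOU = 0.3  # boundary between the slight and severe strata

# palette (RGB)
_SOIL = (148, 124, 94)
_TAN = (205, 175, 125)
_DARK = (92, 62, 40)


class PlacementError(RuntimeError):
    """Raised when pods cannot be placed under the stratum constraint."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic image."""

    n_pods: int = 12
    rotten_fraction: float = 0.3
    adhesion: str = "none"
    image_size: tuple = (320, 320)
    seed: int = 0
    distractor_density: float = 1.0

    def __post_init__(self):
        if self.n_pods < 1:
            raise ValueError("n_pods must be >= 1")
        if not 0.0 <= self.rotten_fraction <= 1.0:
            raise ValueError("rotten_fraction must lie in [0, 1]")
        if self.adhesion not in ADHESION_LEVELS:
            raise ValueError(f"adhesion must be one of {ADHESION_LEVELS}")


def _ellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = math.cos(theta), math.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def _ellipse_bbox(cx: float, cy: float, a: float, b: float, theta: float) -> Box:
    # tight AABB of a rotated ellipse
    ct, st = math.cos(theta), math.sin(theta)
    ex = math.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = math.sqrt((a * st) ** 2 + (b * ct) ** 2)
    return Box(cx, cy, 2 * ex, 2 * ey)


def _place_pods(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample pod geometries satisfying the adhesion stratum."""
    w, h = spec.image_size
    margin = 26
    for _ in range(200):
        geoms = []
        boxes: list[Box] = []
        ok = True
        for i in range(spec.n_pods):
            placed = False
            for _ in range(300):
                a = rng.uniform(11.0, 16.0)
                b = rng.uniform(7.0, 10.5)
                theta = rng.uniform(0, math.pi)
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
                bb = _ellipse_bbox(cx, cy, a, b, theta)
                ious = [iou(bb, other) for other in boxes]
                if spec.adhesion == "none":
                    if all(v == 0.0 for v in ious):
                        placed = True
                elif spec.adhesion == "slight":
                    if all(v <= SLIGHT_MAX_IOU for v in ious):
                        placed = True
                else:  # severe: never forbid overlap
                    placed = True
                if placed:
                    geoms.append((cx, cy, a, b, theta))
                    boxes.append(bb)
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        # stratum verification on the full pairwise IoU set
        pair_ious = [
            iou(boxes[i], boxes[j])
            for i in range(len(boxes)) for j in range(i + 1, len(boxes))
        ]
        if spec.adhesion == "none":
            if not pair_ious or max(pair_ious) == 0.0:
                return geoms, boxes
        elif spec.adhesion == "slight":
            if pair_ious and 0.0 < max(pair_ious) <= SLIGHT_MAX_IOU:
                return geoms, boxes
        else:
            if pair_ious and max(pair_ious) > SLIGHT_MAX_IOU:
                return geoms, boxes
        # constraint not yet met: nudge by re-sampling with overlap encouragement
        if spec.adhesion != "none" and len(geoms) >= 2:
            # force a canonical overlapping pair near an existing pod
            cx0, cy0, a0, b0, t0 = geoms[0]
            shift = a0 * (1.2 if spec.adhesion == "slight" else 0.35)
            cx1 = min(max(cx0 + shift, margin), w - margin)
            geoms[1] = (cx1, cy0, a0, b0, t0)
            boxes[1] = _ellipse_bbox(cx1, cy0, a0, b0, t0)
            pair_ious = [
                iou(boxes[i], boxes[j])
                for i in range(len(boxes)) for j in range(i + 1, len(boxes))
            ]
            mx = max(pair_ious)
            if spec.adhesion == "slight" and 0.0 < mx <= SLIGHT_MAX_IOU:
                return geoms, boxes
            if spec.adhesion == "severe" and mx > SLIGHT_MAX_IOU:
                return geoms, boxes
    raise PlacementError(
        f"could not place {spec.n_pods} pods under stratum {spec.adhesion!r}"
    )


def _draw_distractors(img: np.ndarray, rng: np.random.Generator,
                      density: float) -> None:
    """Curvilinear strokes in the rotten palette (roots/stems)."""
    h, w = img.shape[:2]
    n = int(round(3 * density))
    for _ in range(n):
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        ang = rng.uniform(0, 2 * math.pi)
        color = np.array(_DARK) + rng.integers(-18, 18, 3)
        thickness = rng.integers(1, 3)
        for _ in range(rng.integers(40, 120)):
            ang += rng.normal(0, 0.25)
            x += math.cos(ang) * 2.0
            y += math.sin(ang) * 2.0
            xi, yi = int(x), int(y)
            if 0 <= xi < w and 0 <= yi < h:
                img[max(yi - thickness, 0) : yi + thickness,
                    max(xi - thickness, 0) : xi + thickness] = np.clip(color, 0, 255)


def generate_scene(spec: SceneSpec) -> AnnotatedImage:
    """Render one scene; deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size
    img = np.empty((h, w, 3), dtype=np.uint8)
    base = np.array(_SOIL, dtype=np.float32)
    texture = rng.normal(0, 9, (h, w, 1)).astype(np.float32)
    img[:] = np.clip(base[None, None, :] + texture, 0, 255).astype(np.uint8)
    _draw_distractors(img, rng, spec.distractor_density)

    n_rotten = int(round(spec.n_pods * spec.rotten_fraction))
    classes = ["R"] * n_rotten + ["G"] * (spec.n_pods - n_rotten)
    geoms, boxes = _place_pods(spec, rng)
    annotated = []
    for (cx, cy, a, b, theta), bb, cls in zip(geoms, boxes, classes):
        mask = _ellipse_mask(h, w, cx, cy, a, b, theta)
        if cls == "G":
            fill = np.array(_TAN, dtype=np.float32)
            speck = rng.normal(0, 12, (h, w, 1)).astype(np.float32)
            img[mask] = np.clip(fill + speck, 0, 255).astype(np.uint8)[mask]
        else:
            fill = np.array(_DARK, dtype=np.float32)
            speck = rng.normal(0, 10, (h, w, 1)).astype(np.float32)
            img[mask] = np.clip(fill + speck, 0, 255).astype(np.uint8)[mask]
            # black mottle patches
            mottle = (rng.random((h, w)) < 0.25) & mask
            img[mottle] = np.clip(
                img[mottle].astype(np.int16) - rng.integers(30, 60), 0, 255
            ).astype(np.uint8)
        annotated.append(replace(bb, cls=cls))
    return AnnotatedImage(image=img, boxes=annotated,
                          source_id=f"scene_{spec.adhesion}_{spec.seed:08d}")


def generate_validation_set(n_per_stratum: int, base_spec: SceneSpec | None = None,
                            seed: int = 0) -> list[AnnotatedImage]:
    """n_per_stratum scenes per adhesion stratum with derived per-scene seeds."""
    if n_per_stratum < 1:
        raise ValueError("n_per_stratum must be >= 1")
    base = base_spec or SceneSpec()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(3 * n_per_stratum) % (2**31 - 1)
    rng = np.random.default_rng(seed)
    scenes = []
    k = 0
    for stratum in ADHESION_LEVELS:
        for _ in range(n_per_stratum):
            n_pods = int(rng.integers(max(4, base.n_pods - 4), base.n_pods + 5))
            frac = float(np.clip(rng.normal(base.rotten_fraction, 0.15), 0.0, 1.0))
            spec = replace(base, n_pods=n_pods, rotten_fraction=frac,
                           adhesion=stratum, seed=int(child_seeds[k]))
            scenes.append(generate_scene(spec))
            k += 1
    return scenes


def ground_truth_grading(scenes: Sequence[AnnotatedImage],
                         scale: GradeScale = DEFAULT_SCALE) -> list[GradeRecord]:
    """Grade scenes from their ground-truth labels (perfect-detector oracle)."""
    return [record_from_detections(s.source_id, s.boxes, scale) for s in scenes]


def write_scene_dataset(scenes: Sequence[AnnotatedImage], out_dir) -> Path:
    """Write PNGs, VOC XML, YOLO txt and a manifest CSV for a scene list."""
    from PIL import Image
    import pandas as pd

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "voc").mkdir(exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    rows = []
    for s in scenes:
        Image.fromarray(s.image).save(out / "images" / f"{s.source_id}.png")
        write_voc_xml(s, out / "voc" / f"{s.source_id}.xml")
        write_yolo_txt(s, out / "labels" / f"{s.source_id}.txt")
        rec = record_from_detections(s.source_id, s.boxes)
        stratum = s.source_id.split("_")[1]
        rows.append({
            "image_id": s.source_id, "stratum": stratum,
            "n_G": rec.n_nonrotted, "n_R": rec.n_rotten,
            "rate": round(rec.rate, 6), "grade": rec.grade,
        })
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
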