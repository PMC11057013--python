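"""End-to-end workflow helpers: dataset loading, the four model variants,
smoke training, prediction and evaluation. The command-line interface is a
thin wrapper over these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .arch import (ArchSpec, Detection, Detector, build_detector,
                   decode_and_nms, insert_sa_after_c3, small_arch, tiny_arch)
from .data import AnnotatedImage, read_yolo_txt
from .grading import GradeRecord, record_from_detections, write_reports
from .metrics import EvalSummary, evaluate_detections
from .nn.autograd import Tensor, no_grad
from .training import LossConfig, TrainConfig, fit, images_to_batch, letterbox

__all__ = [
    "VARIANTS", "DatasetItem", "load_yolo_dataset", "dataset_from_scenes",
    "make_variant", "train_variant", "predict", "evaluate_model",
    "run_ablation", "detect_and_grade",
]

VARIANTS = ("baseline", "sa", "eiou", "es")


@dataclass
class DatasetItem:
    image: np.ndarray          # (H, W, 3) uint8
    labels: np.ndarray         # (M, 5): cls, cx, cy, w, h in source pixels
    image_id: str


def dataset_from_scenes(scenes: Sequence[AnnotatedImage]) -> list[DatasetItem]:
    items = []
    for s in scenes:
        rows = [[0 if b.cls == "G" else 1, b.cx, b.cy, b.w, b.h] for b in s.boxes]
        items.append(DatasetItem(
            image=s.image,
            labels=np.asarray(rows, dtype=np.float32).reshape(-1, 5),
            image_id=s.source_id,
        ))
    return items


def load_yolo_dataset(root) -> list[DatasetItem]:
    """Load a directory written by :func:`podrot.scenes.write_scene_dataset`."""
    from PIL import Image

    root = Path(root)
    items = []
    for img_path in sorted((root / "images").glob("*.png")):
        img = np.asarray(Image.open(img_path).convert("RGB"))
        h, w = img.shape[:2]
        boxes = read_yolo_txt(root / "labels" / f"{img_path.stem}.txt", w, h)
        rows = [[0 if b.cls == "G" else 1, b.cx, b.cy, b.w, b.h] for b in boxes]
        items.append(DatasetItem(
            image=img, labels=np.asarray(rows, dtype=np.float32).reshape(-1, 5),
            image_id=img_path.stem,
        ))
    return items


def make_variant(name: str, tiny: bool = True, input_size: Optional[int] = None,
                 seed: int = 0) -> tuple[Detector, LossConfig]:
    """Build one of the 2x2 variants.

    ``baseline``: plain backbone, CIoU. ``sa``: + shuffle attention, CIoU.
    ``eiou``: plain backbone, EIoU. ``es``: both deltas (the improved model).
    """
    if name not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if tiny:
        spec = tiny_arch(input_size=input_size or 160)
    else:
        spec = small_arch(input_size=input_size or 640)
    if name in ("sa", "es"):
        spec = insert_sa_after_c3(spec)
    loss = LossConfig(box_loss="eiou" if name in ("eiou", "es") else "ciou")
    return build_detector(spec, seed=seed), loss


def train_variant(detector: Detector, loss: LossConfig, items: Sequence[DatasetItem],
                  epochs: int = 10, batch_size: int = 8, lr: float = 0.01,
                  seed: int = 0, verbose: bool = False) -> list[float]:
    cfg = TrainConfig(epochs=epochs, batch_size=batch_size, lr=lr, seed=seed,
                      loss=loss)
    return fit(detector, [it.image for it in items], [it.labels for it in items],
               cfg, verbose=verbose)


def predict(detector: Detector, items: Sequence[DatasetItem],
            conf_thresh: float = 0.25, iou_thresh: float = 0.45,
            batch_size: int = 8) -> list[list[Detection]]:
    """Run inference; detections are mapped back to source-image pixels."""
    size = detector.spec.input_size
    detector.set_training(False)
    out: list[list[Detection]] = []
    for start in range(0, len(items), batch_size):
        chunk = items[start : start + batch_size]
        lb = [letterbox(it.image, np.zeros((0, 5)), size) for it in chunk]
        batch = images_to_batch([c[0] for c in lb])
        with no_grad():
            raws = detector(Tensor(batch))
        dets = decode_and_nms(raws, detector.spec, conf_thresh, iou_thresh)
        for it, img_dets in zip(chunk, dets):
            h, w = it.image.shape[:2]
            r = min(size / h, size / w)
            top, left = (size - int(round(h * r))) // 2, (size - int(round(w * r))) // 2
            mapped = []
            for d in img_dets:
                b = d.box
                cx, cy = (b.cx - left) / r, (b.cy - top) / r
                bw, bh = b.w / r, b.h / r
                if bw <= 0 or bh <= 0:
                    continue
                from .boxes import Box
                mapped.append(Detection(
                    box=Box(cx, cy, bw, bh, cls=d.cls, conf=d.conf),
                    cls=d.cls, conf=d.conf,
                ))
            out.append(mapped)
    return out


def evaluate_model(detector: Detector, items: Sequence[DatasetItem],
                   conf_thresh: float = 0.001, nms_iou: float = 0.45,
                   match_iou: float = 0.5) -> EvalSummary:
    """mAP-style evaluation: low confidence floor, matching at IoU 0.5."""
    from .boxes import Box

    preds = predict(detector, items, conf_thresh, nms_iou)
    gts = []
    for it in items:
        gts.append([
            Detection(box=Box(r[1], r[2], r[3], r[4],
                              cls="G" if r[0] == 0 else "R"),
                      cls="G" if r[0] == 0 else "R", conf=1.0)
            for r in it.labels
        ])
    return evaluate_detections(preds, gts, match_iou)


def run_ablation(items_train: Sequence[DatasetItem], items_val: Sequence[DatasetItem],
                 epochs: int = 6, batch_size: int = 8, lr: float = 0.01,
                 seed: int = 0, input_size: int = 128, verbose: bool = False
                 ) -> list[dict]:
    """Train the 2x2 variant grid on a shared split and evaluate mAP@0.5.

    All four variants share the same seed, data and schedule; only the SA
    insertion and the box-loss choice differ.
    """
    rows = []
    for name in VARIANTS:
        det, loss = make_variant(name, tiny=True, input_size=input_size, seed=seed)
        train_variant(det, loss, items_train, epochs=epochs,
                      batch_size=batch_size, lr=lr, seed=seed, verbose=verbose)
        summary = evaluate_model(det, items_val)
        rows.append({
            "variant": name,
            "sa": name in ("sa", "es"),
            "eiou": name in ("eiou", "es"),
            "map": round(summary.map, 2),
            "precision": round(summary.precision, 2),
            "recall": round(summary.recall, 2),
        })
    return rows


def detect_and_grade(detections_per_image: dict[str, Sequence],
                     out_dir) -> list[GradeRecord]:
    """Grade per-image detections and write the report files."""
    records = [
        record_from_detections(image_id, dets)
        for image_id, dets in detections_per_image.items()
    ]
    write_reports(records, out_dir)
    return records
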