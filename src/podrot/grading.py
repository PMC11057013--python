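"""Disease grading: per-image pod counts -> rotten pod rate -> grade level.

The rotten pod rate is R / (G + R). Severity follows a five-level ordinal
scale: level 1 for a rate of exactly 0 (no rotten pods), level 3 for rates in
(0, 0.10], level 5 in (0.10, 0.25], level 7 in (0.25, 0.50], level 9 above
0.50. Interval knots are right-closed, applied uniformly.

Reports: one plain-text count file per image plus an aggregate table (xlsx
with a csv mirror) whose columns are image id, non-rotted count, rotten
count, total, rotten pod rate, grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GradeScale", "GradeRecord", "EmptyImageError",
    "rotten_pod_rate", "grade", "record_from_detections",
    "write_reports", "read_report_csv", "REPORT_COLUMNS",
]

REPORT_COLUMNS = ["image_id", "n_nonrotted", "n_rotten", "total", "rate", "grade"]


class EmptyImageError(ValueError):
    """Raised when a rate is requested for an image with zero pods."""


@dataclass(frozen=True)
class GradeScale:
    """Right-closed rate boundaries mapped onto ordinal levels.

    ``boundaries[i]`` is the upper (inclusive) rate limit of ``levels[i + 1]``
    for i > 0; a rate of exactly ``boundaries[0]`` (= 0) is ``levels[0]``.
    """

    boundaries: tuple = (0.0, 0.10, 0.25, 0.50)
    levels: tuple = (1, 3, 5, 7, 9)

    def __post_init__(self):
        b = self.boundaries
        if not all(x < y for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.levels) != len(b) + 1:
            raise ValueError("need exactly one more level than boundaries")


DEFAULT_SCALE = GradeScale()


def rotten_pod_rate(n_nonrotted: int, n_rotten: int) -> float:
    """R / (G + R); raises :class:`EmptyImageError` when both counts are 0."""
    if n_nonrotted < 0 or n_rotten < 0:
        raise ValueError("counts must be nonnegative")
    total = n_nonrotted + n_rotten
    if total == 0:
        raise EmptyImageError("rotten pod rate undefined for an image with no pods")
    return n_rotten / total


def grade(rate: float, scale: GradeScale = DEFAULT_SCALE) -> int:
    """Map a rotten pod rate onto its ordinal severity level."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    if rate == scale.boundaries[0]:
        return scale.levels[0]
    for upper, level in zip(scale.boundaries[1:], scale.levels[1:-1]):
        if rate <= upper:
            return level
    return scale.levels[-1]


@dataclass(frozen=True)
class GradeRecord:
    image_id: str
    n_nonrotted: int
    n_rotten: int
    rate: float
    grade: int
    empty: bool = False  # flagged when the image had no detections at all

    @property
    def total(self) -> int:
        return self.n_nonrotted + self.n_rotten


def record_from_detections(image_id: str, detections: Iterable,
                           scale: GradeScale = DEFAULT_SCALE) -> GradeRecord:
    """Count detections per class and grade the image.

    An image with zero detections is flagged and graded level 1 with rate 0
    (the rate is undefined at 0/0; a flagged record keeps batch runs alive).
    """
    n_g = n_r = 0
    for det in detections:
        cls = getattr(det, "cls", det)
        if cls == "G":
            n_g += 1
        elif cls == "R":
            n_r += 1
        else:
            raise ValueError(f"unknown detection class {cls!r}")
    if n_g + n_r == 0:
        return GradeRecord(image_id, 0, 0, 0.0, scale.levels[0], empty=True)
    r = rotten_pod_rate(n_g, n_r)
    return GradeRecord(image_id, n_g, n_r, r, grade(r, scale))


def _records_frame(records: Sequence[GradeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "n_nonrotted": r.n_nonrotted,
                "n_rotten": r.n_rotten,
                "total": r.total,
                "rate": round(r.rate, 6),
                "grade": r.grade,
            }
            for r in records
        ],
        columns=REPORT_COLUMNS,
    )


def write_reports(records: Sequence[GradeRecord], out_dir) -> dict[str, Path]:
    """Write per-image txt count files and the aggregate xlsx (+ csv mirror)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    txt_dir = out / "graduation"
    txt_dir.mkdir(exist_ok=True)
    for r in records:
        (txt_dir / f"{r.image_id}.txt").write_text(
            f"image: {r.image_id}\n"
            f"non-rotted: {r.n_nonrotted}\n"
            f"rotten: {r.n_rotten}\n"
            f"total: {r.total}\n"
            f"rotten_pod_rate: {r.rate:.6f}\n"
            f"grade: {r.grade}\n"
        )
    df = _records_frame(records)
    xlsx = out / "grades.xlsx"
    csv = out / "grades.csv"
    df.to_excel(xlsx, index=False)
    df.to_csv(csv, index=False)
    return {"xlsx": xlsx, "csv": csv, "txt_dir": txt_dir}


def read_report_csv(path) -> list[GradeRecord]:
    """Re-parse an aggregate csv back into records."""
    df = pd.read_csv(path)
    return [
        GradeRecord(str(row.image_id), int(row.n_nonrotted), int(row.n_rotten),
                    float(row.rate), int(row.grade))
        for row in df.itertuples()
    ]
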