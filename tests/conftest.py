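import numpy as np
import pytest

from podrot.boxes import Box


def rasterized_iou(a: Box, b: Box, cells: int = 1000) -> float:
    """Independent IoU oracle: count covered cells on a cells x cells grid.

    The grid spans the joint bounding box; cell-center membership is tested
    per axis and the 2-D union/intersection counts are assembled column-wise
    (boxes are products of intervals, so this equals the full 2-D count).
    """
    x_lo = min(a.x1, b.x1)
    x_hi = max(a.x2, b.x2)
    y_lo = min(a.y1, b.y1)
    y_hi = max(a.y2, b.y2)
    xs = np.linspace(x_lo, x_hi, cells, endpoint=False) + (x_hi - x_lo) / (2 * cells)
    ys = np.linspace(y_lo, y_hi, cells, endpoint=False) + (y_hi - y_lo) / (2 * cells)
    ax = (xs >= a.x1) & (xs <= a.x2)
    bx = (xs >= b.x1) & (xs <= b.x2)
    ay = (ys >= a.y1) & (ys <= a.y2)
    by = (ys >= b.y1) & (ys <= b.y2)
    n_ay, n_by = np.count_nonzero(ay), np.count_nonzero(by)
    n_aby = np.count_nonzero(ay | by)
    both_x = np.count_nonzero(ax & bx)
    only_ax = np.count_nonzero(ax & ~bx)
    only_bx = np.count_nonzero(~ax & bx)
    union = both_x * n_aby + only_ax * n_ay + only_bx * n_by
    if union == 0:
        return 0.0
    inter = both_x * np.count_nonzero(ay & by)
    return inter / union


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, lo=0.0, hi=100.0, max_side=40.0, cls=None, conf=None) -> Box:
    return Box(
        cx=rng.uniform(lo, hi),
        cy=rng.uniform(lo, hi),
        w=rng.uniform(1.0, max_side),
        h=rng.uniform(1.0, max_side),
        cls=cls,
        conf=conf,
    )
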