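"""Box geometry and regression-loss behavior."""

import math

import numpy as np
import pytest

from podrot.boxes import Box, InvalidBoxError, iou
from podrot.losses import (InvalidLossError, LossBreakdown, ciou_loss,
                           eiou_loss, focal_eiou_loss, regression_terms,
                           total_loss)

from conftest import random_box, rasterized_iou


class TestIoU:
    def test_identical_boxes(self):
        b = Box(3, 4, 5, 6)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 2, 2), Box(10, 10, 2, 2)) == 0.0

    def test_partial_overlap_known_value(self):
        # derived from the rasterization oracle: overlap 1x1, union 7
        assert iou(Box(1, 1, 2, 2), Box(2, 2, 2, 2)) == pytest.approx(1 / 7)

    def test_symmetry(self, rng):
        for _ in range(50):
            a, b = random_box(rng), random_box(rng)
            assert iou(a, b) == pytest.approx(iou(b, a))

    def test_invalid_box_rejected(self):
        with pytest.raises(InvalidBoxError):
            Box(0, 0, 0, 2)
        with pytest.raises(InvalidBoxError):
            Box(0, 0, 2, -1)

    def test_agrees_with_rasterization_oracle(self, rng):
        worst = 0.0
        for _ in range(1000):
            a, b = random_box(rng), random_box(rng)
            worst = max(worst, abs(iou(a, b) - rasterized_iou(a, b)))
        assert worst < 1e-3


class TestRegressionTerms:
    def test_identical_boxes_zero_terms(self):
        b = Box(5, 5, 3, 2)
        t = regression_terms(b, b)
        assert t.iou == 1.0
        assert t.center_dist_sq == 0.0
        assert t.enclosure_diag_sq == 0.0
        assert t.v == 0.0

    def test_disjoint_pair_hand_geometry(self):
        t = regression_terms(Box(0, 0, 2, 2), Box(10, 0, 2, 2))
        assert t.iou == 0.0
        assert t.alpha == 0.0  # IoU < 0.5 branch
        assert t.center_dist_sq == pytest.approx(100.0)
        assert t.enclosure_w == pytest.approx(12.0)
        assert t.enclosure_h == pytest.approx(2.0)
        assert t.enclosure_diag_sq == pytest.approx(148.0)

    def test_equal_aspect_ratio_v_zero(self):
        t = regression_terms(Box(0, 0, 2, 4), Box(5, 5, 3, 6))
        assert t.v == pytest.approx(0.0)

    def test_alpha_active_branch(self):
        # large overlap, different aspect: IoU >= 0.5 turns alpha on
        t = regression_terms(Box(0, 0, 10, 10), Box(0, 0, 10, 14))
        assert t.iou >= 0.5
        assert t.v > 0
        assert t.alpha == pytest.approx(t.v / (1 - t.iou + t.v))

    def test_invariants_random(self, rng):
        for _ in range(200):
            a, b = random_box(rng), random_box(rng)
            t = regression_terms(a, b)
            assert 0 <= t.iou <= 1
            assert t.center_dist_sq <= t.enclosure_diag_sq + 1e-9
            assert t.enclosure_w >= abs(a.cx - b.cx)
            assert t.v >= 0
            assert 0 <= t.alpha <= 1


class TestCIoU:
    def test_identical_is_zero(self):
        b = Box(1, 2, 3, 4)
        assert ciou_loss(b, b) == 0.0

    def test_disjoint_hand_value(self):
        assert ciou_loss(Box(0, 0, 2, 2), Box(10, 0, 2, 2)) == pytest.approx(
            1 + 100 / 148, rel=1e-6
        )

    def test_concentric_same_aspect_reduces_to_one_minus_iou(self):
        p, g = Box(0, 0, 2, 2), Box(0, 0, 4, 4)
        assert ciou_loss(p, g) == pytest.approx(1 - iou(p, g), rel=1e-6)


class TestEIoU:
    def test_identical_is_zero(self):
        b = Box(1, 2, 3, 4)
        assert eiou_loss(b, b) == 0.0

    def test_equal_size_reduces_to_iou_plus_distance(self, rng):
        for _ in range(50):
            g = random_box(rng)
            p = Box(g.cx + rng.uniform(-5, 5), g.cy + rng.uniform(-5, 5), g.w, g.h)
            t = regression_terms(p, g)
            expect = (1 - t.iou) + t.center_dist_sq / (t.enclosure_diag_sq + 1e-9)
            assert eiou_loss(p, g) == pytest.approx(expect, rel=1e-9)

    def test_concentric_scaled_hand_value(self):
        # IoU = 4/16; width and height terms each (2-4)^2 / 4^2 = 0.25
        assert eiou_loss(Box(0, 0, 2, 2), Box(0, 0, 4, 4)) == pytest.approx(
            1.25, rel=1e-6
        )

    def test_equal_size_matches_ciou(self, rng):
        # equal sizes: the aspect term of CIoU and the wh terms of EIoU vanish
        for _ in range(100):
            g = random_box(rng)
            p = Box(g.cx + rng.uniform(-10, 10), g.cy + rng.uniform(-10, 10), g.w, g.h)
            assert eiou_loss(p, g) == pytest.approx(ciou_loss(p, g), abs=1e-9)

    def test_symmetry(self, rng):
        for _ in range(100):
            a, b = random_box(rng), random_box(rng)
            assert eiou_loss(a, b) == pytest.approx(eiou_loss(b, a), rel=1e-9)

    def test_zero_iff_identical(self, rng):
        for _ in range(100):
            a, b = random_box(rng), random_box(rng)
            if (a.cx, a.cy, a.w, a.h) != (b.cx, b.cy, b.w, b.h):
                assert eiou_loss(a, b) > 0
                assert ciou_loss(a, b) > 0

    def test_monotone_in_axis_translation(self, rng):
        # moving the prediction further away along x never decreases the loss
        g = Box(50, 50, 10, 8)
        for _ in range(20):
            base = rng.uniform(0, 40)
            losses = [
                eiou_loss(Box(50 + base + d, 50, 10, 8), g) for d in np.linspace(0, 60, 30)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(losses, losses[1:]))


class TestFocalEIoU:
    def test_gamma_zero_recovers_eiou(self, rng):
        for _ in range(20):
            a, b = random_box(rng), random_box(rng)
            assert focal_eiou_loss(a, b, gamma=0.0) == eiou_loss(a, b)

    def test_disjoint_pair_is_zero(self):
        assert focal_eiou_loss(Box(0, 0, 2, 2), Box(50, 50, 2, 2), gamma=0.5) == 0.0

    def test_identical_is_zero(self):
        b = Box(0, 0, 2, 2)
        assert focal_eiou_loss(b, b, gamma=2.0) == 0.0

    def test_negative_gamma_rejected(self):
        with pytest.raises(InvalidLossError):
            focal_eiou_loss(Box(0, 0, 1, 1), Box(0, 0, 1, 1), gamma=-1.0)


class TestTotalLoss:
    def test_sum_and_commutativity(self):
        assert total_loss(LossBreakdown(0, 0, 0)) == 0.0
        assert total_loss(LossBreakdown(0.1, 0.2, 0.3)) == pytest.approx(0.6)
        assert total_loss(LossBreakdown(0.3, 0.1, 0.2)) == pytest.approx(0.6)

    def test_negative_component_rejected(self):
        with pytest.raises(InvalidLossError):
            total_loss(LossBreakdown(-0.1, 0.2, 0.3))

    def test_breakdown_total_property(self):
        p = LossBreakdown(1.0, 2.0, 3.0)
        assert p.total == pytest.approx(p.l_cla + p.l_loc + p.l_conf)
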