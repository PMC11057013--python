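"""Matching, precision/recall, AP against a brute-force envelope, CP, k-fold."""

import numpy as np
import pytest

from podrot.arch import Detection
from podrot.boxes import Box
from podrot.metrics import (ImageLevelTally, UndefinedMetricError,
                            average_precision, comparison_precision,
                            evaluate_detections, image_level_correct,
                            kfold_splits, match_detections, mean_ap,
                            precision, recall)


def det(cx, cy, w, h, cls="G", conf=1.0):
    return Detection(box=Box(cx, cy, w, h, cls=cls, conf=conf), cls=cls, conf=conf)


def gt(cx, cy, w, h, cls="G"):
    return Detection(box=Box(cx, cy, w, h, cls=cls), cls=cls, conf=1.0)


def envelope_ap_oracle(scores, flags, n_gt):
    """Brute-force 101-point AP: for each recall grid point, the best
    precision among all prediction-list prefixes reaching that recall."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    flags = np.asarray(flags, dtype=bool)[order]
    prefix_prec = []
    prefix_rec = []
    tp = fp = 0
    for f in flags:
        tp, fp = tp + int(f), fp + int(not f)
        prefix_prec.append(tp / (tp + fp))
        prefix_rec.append(tp / n_gt)
    total = 0.0
    for r in np.linspace(0, 1, 101):
        best = 0.0
        for p_, r_ in zip(prefix_prec, prefix_rec):
            if r_ >= r - 1e-12:
                best = max(best, p_)
        total += best
    return total / 101


class TestMatching:
    def test_perfect_predictions(self):
        gts = [gt(10, 10, 4, 4, "G"), gt(30, 30, 6, 6, "R")]
        preds = [det(10, 10, 4, 4, "G"), det(30, 30, 6, 6, "R")]
        m = match_detections(preds, gts, 0.5)
        assert m.totals() == (2, 0, 0)

    def test_stray_prediction(self):
        gts = [gt(10, 10, 4, 4, "G"), gt(30, 30, 4, 4, "G")]
        preds = [det(90, 90, 4, 4, "G")]
        m = match_detections(preds, gts, 0.5)
        assert m.totals() == (0, 1, 2)

    def test_two_preds_one_gt_greedy(self):
        gts = [gt(10, 10, 8, 8, "G")]
        preds = [det(10, 10, 8, 8, "G", conf=0.9), det(11, 10, 8, 8, "G", conf=0.8)]
        m = match_detections(preds, gts, 0.5)
        assert (m.tp["G"], m.fp["G"]) == (1, 1)
        # the higher-confidence prediction owns the match
        assert m.pairs[0][1] == 0

    def test_class_separation(self):
        gts = [gt(10, 10, 4, 4, "G")]
        preds = [det(10, 10, 4, 4, "R")]
        m = match_detections(preds, gts, 0.5)
        assert m.fp["R"] == 1 and m.fn["G"] == 1 and sum(m.tp.values()) == 0

    def test_count_identities(self, rng):
        from conftest import random_box
        for _ in range(30):
            gts = [gt(*random_box(rng).corners()[:2], 6, 6,
                      cls=("G", "R")[rng.integers(2)]) for _ in range(5)]
            preds = [det(*random_box(rng).corners()[:2], 6, 6,
                         cls=("G", "R")[rng.integers(2)],
                         conf=float(rng.random())) for _ in range(6)]
            m = match_detections(preds, gts, 0.5)
            for c in ("G", "R"):
                assert m.tp[c] + m.fn[c] == sum(1 for g in gts if g.cls == c)
                assert m.tp[c] + m.fp[c] == sum(1 for p in preds if p.cls == c)


class TestScalarMetrics:
    @pytest.mark.parametrize("tp,fp,expect", [(9, 1, 90.0), (0, 5, 0.0), (7, 0, 100.0)])
    def test_precision(self, tp, fp, expect):
        assert precision(tp, fp) == expect

    @pytest.mark.parametrize("tp,fn,expect", [(9, 1, 90.0), (0, 5, 0.0), (7, 0, 100.0)])
    def test_recall(self, tp, fn, expect):
        assert recall(tp, fn) == expect

    def test_undefined_cases(self):
        with pytest.raises(UndefinedMetricError):
            precision(0, 0)
        with pytest.raises(UndefinedMetricError):
            recall(0, 0)

    def test_scale_invariance(self):
        assert precision(9, 1) == precision(90, 10)
        assert recall(3, 2) == recall(30, 20)

    def test_mean_ap(self):
        assert mean_ap([0.8, 1.0]) == pytest.approx(90.0)
        assert mean_ap([0.37, 0.37]) == pytest.approx(37.0)
        assert mean_ap([0.2, 0.9]) == mean_ap([0.9, 0.2])
        with pytest.raises(UndefinedMetricError):
            mean_ap([])


class TestAveragePrecision:
    def test_single_perfect_prediction(self):
        assert average_precision([0.9], [True], 1) == pytest.approx(1.0)

    def test_all_false(self):
        assert average_precision([0.9, 0.8], [False, False], 3) == 0.0

    def test_no_predictions(self):
        assert average_precision([], [], 2) == 0.0

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(UndefinedMetricError):
            average_precision([0.5], [True], 0)

    def test_small_case_against_envelope(self):
        scores = [0.9, 0.8, 0.7, 0.6]
        flags = [True, False, True, True]
        n_gt = 3
        assert average_precision(scores, flags, n_gt) == pytest.approx(
            envelope_ap_oracle(scores, flags, n_gt), abs=1e-12
        )

    def test_oracle_agreement_500_random_instances(self, rng):
        """AP equals an exhaustive PR-envelope construction within 1e-9."""
        for _ in range(500):
            n_gt = int(rng.integers(1, 11))
            n_pred = int(rng.integers(0, 11))
            scores = rng.random(n_pred)
            # flags constrained: cannot have more TPs than ground truths
            flags = np.zeros(n_pred, dtype=bool)
            n_tp = int(rng.integers(0, min(n_gt, n_pred) + 1)) if n_pred else 0
            flags[rng.choice(n_pred, size=n_tp, replace=False)] = True
            got = average_precision(scores.tolist(), flags.tolist(), n_gt)
            want = envelope_ap_oracle(scores.tolist(), flags.tolist(), n_gt)
            assert abs(got - want) < 1e-9


class TestImageLevel:
    def test_perfect_image(self):
        gts = [gt(10, 10, 4, 4, "G"), gt(30, 30, 4, 4, "R")]
        preds = [det(10, 10, 4, 4, "G"), det(30, 30, 4, 4, "R")]
        assert image_level_correct(preds, gts, 0.5)

    def test_missed_pod_disqualifies(self):
        gts = [gt(10, 10, 4, 4, "G"), gt(30, 30, 4, 4, "R")]
        preds = [det(10, 10, 4, 4, "G")]
        assert not image_level_correct(preds, gts, 0.5)

    def test_extra_box_disqualifies(self):
        gts = [gt(10, 10, 4, 4, "G")]
        preds = [det(10, 10, 4, 4, "G"), det(50, 50, 4, 4, "G")]
        assert not image_level_correct(preds, gts, 0.5)


class TestComparisonPrecision:
    def test_rounding_to_two_decimals(self):
        assert comparison_precision(ImageLevelTally(142, 150)) == 94.67
        assert comparison_precision(ImageLevelTally(130, 150)) == 86.67
        assert comparison_precision(ImageLevelTally(125, 150)) == 83.33
        assert comparison_precision(ImageLevelTally(131, 150)) == 87.33

    def test_extremes(self):
        assert comparison_precision(ImageLevelTally(50, 50)) == 100.0
        assert comparison_precision(ImageLevelTally(0, 20)) == 0.0

    def test_invalid_tally(self):
        with pytest.raises(ValueError):
            ImageLevelTally(5, 3)
        with pytest.raises(UndefinedMetricError):
            comparison_precision(ImageLevelTally(0, 0))


class TestKFold:
    def test_five_fold_of_ten(self):
        splits = kfold_splits(10, 5, seed=0)
        assert len(splits) == 5
        assert all(len(val) == 2 for _, val in splits)

    def test_partition_properties(self):
        splits = kfold_splits(23, 5, seed=3)
        all_val = np.concatenate([val for _, val in splits])
        assert sorted(all_val.tolist()) == list(range(23))
        for train, val in splits:
            assert set(train).isdisjoint(val)
            assert sorted(np.concatenate([train, val]).tolist()) == list(range(23))

    def test_seeded_determinism(self):
        a = kfold_splits(17, 5, seed=9)
        b = kfold_splits(17, 5, seed=9)
        for (t1, v1), (t2, v2) in zip(a, b):
            np.testing.assert_array_equal(v1, v2)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            kfold_splits(3, 5, seed=0)
        with pytest.raises(ValueError):
            kfold_splits(10, 1, seed=0)


class TestEvaluateDetections:
    def test_perfect_detector_is_all_hundreds(self):
        gts_imgs = [
            [gt(10, 10, 4, 4, "G"), gt(30, 30, 4, 4, "R")],
            [gt(50, 50, 6, 6, "G")],
        ]
        s = evaluate_detections(gts_imgs, gts_imgs, 0.5)
        assert s.precision == 100.0
        assert s.recall == 100.0
        assert s.map == pytest.approx(100.0)
        assert s.cp == 100.0
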