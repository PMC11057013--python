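"""Annotation formats, resize, augmentation and dataset bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from podrot.boxes import Box
from podrot.data import (AUGMENT_OPS, AnnotatedImage, LabelCensus,
                         UnknownClassError, augment, census, random_combo,
                         read_voc_xml, read_yolo_txt, resize_with_boxes,
                         sample_combo_ops, split_dataset, write_voc_xml,
                         write_yolo_txt)

VOC_XML = """<annotation>
  <filename>plant_001</filename>
  <size><width>200</width><height>400</height><depth>3</depth></size>
  {objects}
</annotation>
"""

OBJ = """<object><name>{name}</name>
  <bndbox><xmin>{x1}</xmin><ymin>{y1}</ymin><xmax>{x2}</xmax><ymax>{y2}</ymax></bndbox>
</object>"""


def make_ann(rng, w=120, h=90, boxes=None) -> AnnotatedImage:
    img = rng.integers(0, 255, (h, w, 3), dtype=np.uint8)
    if boxes is None:
        boxes = [Box(40, 30, 20, 16, cls="G"), Box(80, 60, 18, 14, cls="R")]
    return AnnotatedImage(img, boxes, "fixture")


class TestVocXml:
    def test_read_counts_and_classes(self, tmp_path):
        objs = "".join(
            [OBJ.format(name="G", x1=10, y1=10, x2=30, y2=50)] * 3
            + [OBJ.format(name="R", x1=100, y1=100, x2=150, y2=180)]
        )
        p = tmp_path / "a.xml"
        p.write_text(VOC_XML.format(objects=objs))
        name, (w, h), boxes = read_voc_xml(p)
        assert (name, w, h) == ("plant_001", 200, 400)
        c = census([boxes])
        assert (c.n_G, c.n_R, c.total) == (3, 1, 4)

    def test_corner_to_center_conversion(self, tmp_path):
        p = tmp_path / "a.xml"
        p.write_text(VOC_XML.format(
            objects=OBJ.format(name="G", x1=10, y1=10, x2=30, y2=50)))
        _, _, boxes = read_voc_xml(p)
        b = boxes[0]
        assert (b.cx, b.cy, b.w, b.h) == (20, 30, 20, 40)

    def test_empty_object_list(self, tmp_path):
        p = tmp_path / "a.xml"
        p.write_text(VOC_XML.format(objects=""))
        _, _, boxes = read_voc_xml(p)
        assert boxes == []

    def test_unknown_class_is_reported_by_name(self, tmp_path):
        p = tmp_path / "a.xml"
        p.write_text(VOC_XML.format(
            objects=OBJ.format(name="weed", x1=1, y1=1, x2=5, y2=5)))
        with pytest.raises(UnknownClassError, match="weed"):
            read_voc_xml(p)

    def test_voc_yolo_voc_round_trip_within_a_pixel(self, rng, tmp_path):
        ann = make_ann(rng, w=200, h=400,
                       boxes=[Box(100, 200, 20, 40, cls="G"),
                              Box(55.5, 120.25, 31, 17, cls="R")])
        write_voc_xml(ann, tmp_path / "a.xml")
        _, _, boxes1 = read_voc_xml(tmp_path / "a.xml")
        write_yolo_txt(AnnotatedImage(ann.image, boxes1, "a"), tmp_path / "a.txt")
        boxes2 = read_yolo_txt(tmp_path / "a.txt", 200, 400)
        for b0, b2 in zip(ann.boxes, boxes2):
            assert abs(b0.cx - b2.cx) < 1.0
            assert abs(b0.cy - b2.cy) < 1.0
            assert abs(b0.w - b2.w) < 1.0
            assert abs(b0.h - b2.h) < 1.0
            assert b0.cls == b2.cls


class TestYoloTxt:
    def test_known_normalization(self, rng, tmp_path):
        ann = make_ann(rng, w=200, h=400,
                       boxes=[Box(100, 200, 20, 40, cls="G")])
        write_yolo_txt(ann, tmp_path / "a.txt")
        assert (tmp_path / "a.txt").read_text().strip() == \
            "0 0.500000 0.500000 0.100000 0.100000"

    def test_empty_annotation_empty_file(self, rng, tmp_path):
        ann = make_ann(rng, boxes=[])
        write_yolo_txt(ann, tmp_path / "a.txt")
        assert (tmp_path / "a.txt").read_text() == ""

    def test_round_trip_normalized(self, rng, tmp_path):
        ann = make_ann(rng)
        write_yolo_txt(ann, tmp_path / "a.txt")
        back = read_yolo_txt(tmp_path / "a.txt", ann.width, ann.height)
        for b0, b1 in zip(ann.boxes, back):
            assert b0.cx / ann.width == pytest.approx(b1.cx / ann.width, abs=1e-6)
            assert b0.h / ann.height == pytest.approx(b1.h / ann.height, abs=1e-6)


class TestResize:
    def test_capture_pipeline_dimensions_scale_boxes(self, rng):
        # 4032 x 1816 capture resized to 1400 x 631
        ann = AnnotatedImage(
            rng.integers(0, 255, (1816 // 8, 4032 // 8, 3), dtype=np.uint8),
            [Box(2016 / 8, 908 / 8, 100 / 8, 80 / 8, cls="G")], "big")
        tw, th = 1400 // 8, 631 // 8
        out = resize_with_boxes(ann, tw, th)
        sx, sy = tw / (4032 // 8), th / (1816 // 8)
        b = out.boxes[0]
        assert b.cx == pytest.approx(2016 / 8 * sx)
        assert b.h == pytest.approx(80 / 8 * sy)

    def test_identity_resize(self, rng):
        ann = make_ann(rng)
        out = resize_with_boxes(ann, ann.width, ann.height)
        assert out.boxes == ann.boxes
        np.testing.assert_array_equal(out.image, ann.image)

    def test_center_box_stays_centered(self, rng):
        ann = make_ann(rng, w=100, h=80, boxes=[Box(50, 40, 10, 10, cls="G")])
        out = resize_with_boxes(ann, 37, 53)
        assert out.boxes[0].cx == pytest.approx(37 / 2)
        assert out.boxes[0].cy == pytest.approx(53 / 2)


class TestAugment:
    def test_hflip_is_involution(self, rng):
        ann = make_ann(rng)
        twice = augment(augment(ann, ["hflip"], seed=1), ["hflip"], seed=1)
        np.testing.assert_array_equal(twice.image, ann.image)
        for b0, b1 in zip(ann.boxes, twice.boxes):
            assert b0.cx == pytest.approx(b1.cx)

    def test_vflip_is_involution(self, rng):
        ann = make_ann(rng)
        twice = augment(augment(ann, ["vflip"], seed=1), ["vflip"], seed=1)
        np.testing.assert_array_equal(twice.image, ann.image)

    def test_noise_only_leaves_boxes(self, rng):
        ann = make_ann(rng)
        out = augment(ann, ["noise"], seed=7)
        assert out.boxes == ann.boxes
        assert not np.array_equal(out.image, ann.image)

    def test_translation_shifts_centers_exactly(self, rng):
        # big image, small centered box: the box always survives
        ann = make_ann(rng, w=200, h=200, boxes=[Box(100, 100, 10, 10, cls="G")])
        out = augment(ann, ["translation"], seed=3)
        assert len(out.boxes) == 1
        dx = out.boxes[0].cx - 100
        dy = out.boxes[0].cy - 100
        assert dx == int(dx) and dy == int(dy)
        # pixels moved consistently: sample the box center pixel
        assert np.array_equal(
            out.image[int(100 + dy), int(100 + dx)], ann.image[100, 100])

    def test_deterministic_given_seed(self, rng):
        ann = make_ann(rng)
        a = augment(ann, ["noise", "rotation"], seed=11)
        b = augment(ann, ["noise", "rotation"], seed=11)
        np.testing.assert_array_equal(a.image, b.image)
        assert a.boxes == b.boxes

    def test_empty_ops_rejected(self, rng):
        with pytest.raises(ValueError):
            augment(make_ann(rng), [], seed=0)

    def test_geometric_ops_preserve_class_counts(self, rng):
        # rotation/translation/flips never change counts for interior boxes
        ann = make_ann(rng, w=300, h=300,
                       boxes=[Box(150, 150, 12, 10, cls="G"),
                              Box(140, 160, 10, 12, cls="R")])
        for op in ("rotation", "hflip", "vflip"):
            out = augment(ann, [op], seed=5)
            assert census([out.boxes]).total == 2


class TestRandomCombo:
    def test_zero_ops_is_identity(self, rng):
        ann = make_ann(rng)
        out = random_combo(ann, 0, seed=9)
        np.testing.assert_array_equal(out.image, ann.image)

    def test_same_seed_identical_bytes(self, rng):
        ann = make_ann(rng)
        a = random_combo(ann, 5, seed=21)
        b = random_combo(ann, 5, seed=21)
        np.testing.assert_array_equal(a.image, b.image)

    def test_subset_sampling_uniform_chi_square(self):
        # 5 of 7 primitives: 21 possible subsets, uniform under the null
        from itertools import combinations

        subsets = {frozenset(c): 0 for c in combinations(AUGMENT_OPS, 5)}
        n_draws = 10_000
        for seed in range(n_draws):
            subsets[frozenset(sample_combo_ops(5, seed))] += 1
        counts = np.array(list(subsets.values()))
        assert counts.sum() == n_draws
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01


class TestSplitCensus:
    def test_split_sizes_full_dataset_scale(self):
        train, test = split_dataset(list(range(12_000)), 0.9, seed=0)
        assert (len(train), len(test)) == (10_800, 1_200)

    def test_split_small(self):
        train, test = split_dataset(list(range(10)), 0.9, seed=0)
        assert (len(train), len(test)) == (9, 1)

    def test_split_disjoint_exhaustive(self):
        items = list(range(101))
        train, test = split_dataset(items, 0.73, seed=4)
        assert sorted(train + test) == items
        assert set(train).isdisjoint(test)

    def test_split_empty_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([], 0.9, seed=0)

    def test_census_totals(self):
        c = LabelCensus(56_730, 27_120)
        assert c.total == 83_850

    def test_census_empty_and_additive(self, rng):
        assert census([]).total == 0
        a = make_ann(rng)
        c1 = census([a])
        c2 = census([a, a])
        assert (c1 + c1) == c2
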