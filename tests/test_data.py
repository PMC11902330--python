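"""Label I/O, augmentation algebra, splitting, and the scene generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gpcyolo.boxes import Box
from gpcyolo.data import (LabeledImage, SceneSpec, augment_dataset,
                          flip_augment, generate_scenes, load_dataset_dir,
                          read_yolo_labels, rotate_augment, split_dataset,
                          write_yolo_labels)


def li(image_id, boxes=(), wh=(100, 100)):
    return LabeledImage(image_id, wh[0], wh[1], list(boxes))


class TestLabelIO:
    def test_parse_single_line(self, tmp_path):
        p = tmp_path / "a.txt"
        p.write_text("0 0.5 0.5 0.2 0.3\n")
        img = read_yolo_labels(p)
        b = img.boxes[0]
        assert (b.class_id, b.cx, b.cy, b.w, b.h) == (0, 0.5, 0.5, 0.2, 0.3)

    def test_round_trip_on_random_fixture(self, tmp_path, rng):
        boxes = [Box(*np.round(rng.uniform(0.2, 0.6, 4), 6),
                     class_id=int(rng.integers(0, 3))) for _ in range(20)]
        src = li("x", boxes)
        p = tmp_path / "x.txt"
        write_yolo_labels(src, p)
        back = read_yolo_labels(p)
        for a, b in zip(src.boxes, back.boxes):
            assert (a.class_id, a.cx, a.cy, a.w, a.h) \
                == (b.class_id, b.cx, b.cy, b.w, b.h)

    def test_out_of_range_coordinate_names_file_and_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2 0.3\n0 1.5 0.5 0.2 0.3\n")
        with pytest.raises(ValueError, match=r"bad\.txt:2.*cx"):
            read_yolo_labels(p)

    def test_wrong_field_count_reports_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 0.5 0.5 0.2\n")
        with pytest.raises(ValueError, match=":1"):
            read_yolo_labels(p)


class TestRotationsAndFlips:
    def test_180_degree_example(self):
        img = li("a", [Box(0.2, 0.3, 0.1, 0.2, class_id=0)])
        b = rotate_augment(img, 180).boxes[0]
        assert (b.cx, b.cy, b.w, b.h) == pytest.approx((0.8, 0.7, 0.1, 0.2))

    def test_90_degree_swaps_canvas_and_coords(self):
        img = li("a", [Box(0.2, 0.3, 0.1, 0.2, class_id=0)], wh=(200, 100))
        out = rotate_augment(img, 90)
        assert (out.width, out.height) == (100, 200)
        b = out.boxes[0]
        assert (b.cx, b.cy, b.w, b.h) == pytest.approx((0.7, 0.2, 0.2, 0.1))

    def test_four_quarter_turns_are_identity(self):
        img = li("a", [Box(0.3, 0.1, 0.15, 0.05, class_id=2)], wh=(80, 60))
        out = img
        for _ in range(4):
            out = rotate_augment(out, 90)
        b, a = out.boxes[0], img.boxes[0]
        assert (b.cx, b.cy, b.w, b.h) == pytest.approx((a.cx, a.cy, a.w, a.h))
        assert (out.width, out.height) == (80, 60)

    def test_rejects_other_angles(self):
        with pytest.raises(ValueError):
            rotate_augment(li("a"), 45)

    def test_flip_examples_and_involution(self):
        img = li("a", [Box(0.2, 0.3, 0.1, 0.2, class_id=1),
                       Box(0.5, 0.6, 0.2, 0.2, class_id=0)])
        out = flip_augment(img)
        assert out.boxes[0].cx == pytest.approx(0.8)
        assert out.boxes[1].cx == pytest.approx(0.5)  # axis fixed point
        back = flip_augment(out)
        for a, b in zip(img.boxes, back.boxes):
            assert a.cx == pytest.approx(b.cx)

    def test_pixels_follow_boxes_under_rotation(self, rng):
        """A bright patch's pixel bounding box tracks the label transform."""
        arr = np.zeros((40, 60, 3), dtype=np.uint8)
        arr[4:12, 6:18] = 255      # rows 4-12, cols 6-18
        img = li("a", [Box(12 / 60, 8 / 40, 12 / 60, 8 / 40, class_id=0)],
                 wh=(60, 40))
        for angle in (90, 180, 270):
            out, rot = rotate_augment(img, angle, arr)
            ys, xs = np.nonzero(rot[..., 0])
            b = out.boxes[0]
            assert b.cx * out.width == pytest.approx((xs.min() + xs.max() + 1) / 2, abs=0.51)
            assert b.cy * out.height == pytest.approx((ys.min() + ys.max() + 1) / 2, abs=0.51)

    @given(st.permutations([90, 180, 270]).map(tuple))
    def test_class_multiset_conserved(self, angles):
        img = li("a", [Box(0.4, 0.4, 0.1, 0.1, class_id=c) for c in (0, 1, 1, 2)])
        out = img
        for a in angles:
            out = rotate_augment(out, a)
        assert sorted(b.class_id for b in out.boxes) == [0, 1, 1, 2]
        assert len(out.boxes) == len(img.boxes)


class TestAugmentPipeline:
    @given(st.integers(1, 60), st.integers(0, 60))
    def test_count_formula(self, n, m):
        m = min(m, n)
        images = [li(f"i{k}") for k in range(n)]
        minority = {f"i{k}" for k in range(m)}
        out = augment_dataset(images, minority)
        assert len(out) == (n - m + 4 * m) * 2
        assert len({im.image_id for im in out}) == len(out)

    def test_small_worked_example(self):
        out = augment_dataset([li(f"i{k}") for k in range(10)],
                              {"i0", "i1", "i2"})
        assert len(out) == 38

    def test_flip_only_case(self):
        out = augment_dataset([li(f"i{k}") for k in range(7)], set())
        assert len(out) == 14

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            augment_dataset([li("a"), li("a")], set())

    def test_unknown_minority_id_rejected(self):
        with pytest.raises(ValueError):
            augment_dataset([li("a")], {"zz"})


class TestSplit:
    def test_published_dataset_arithmetic(self):
        """1249 images with 304 minority -> 1216 minority-derived pre-flip,
        4322 total, and an 8:1:1 split of 3457/432/433."""
        images = [li(f"img{k}") for k in range(1249)]
        minority = {f"img{k}" for k in range(304)}
        expanded = augment_dataset(images, minority)
        pre_flip = [im for im in expanded if not im.image_id.endswith("_flip")]
        minority_derived = [im for im in pre_flip
                            if im.image_id.split("_rot")[0] in minority]
        assert len(minority_derived) == 1216
        assert len(expanded) == 4322
        sp = split_dataset(expanded, (0.8, 0.1, 0.1), seed=0)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (3457, 432, 433)

    def test_exact_ratio_case(self):
        sp = split_dataset([li(f"i{k}") for k in range(10)])
        assert (len(sp.train), len(sp.val), len(sp.test)) == (8, 1, 1)

    def test_seed_determinism(self):
        images = [li(f"i{k}") for k in range(50)]
        a = split_dataset(images, seed=3)
        b = split_dataset(images, seed=3)
        c = split_dataset(images, seed=4)
        assert a.train == b.train and a.val == b.val and a.test == b.test
        assert a.train != c.train
        assert sorted(c.train + c.val + c.test) == sorted(im.image_id for im in images)

    def test_too_few_images(self):
        with pytest.raises(ValueError):
            split_dataset([li("a"), li("b")])


class TestSceneGenerator:
    def test_determinism_is_byte_exact(self):
        spec = SceneSpec(n_images=3, image_size=96, rng_seed=11)
        a = generate_scenes(spec)
        b = generate_scenes(spec)
        for (la, ia), (lb, ib) in zip(a, b):
            np.testing.assert_array_equal(ia, ib)
            assert [(x.class_id, x.cx, x.cy, x.w, x.h) for x in la.boxes] \
                == [(x.class_id, x.cx, x.cy, x.w, x.h) for x in lb.boxes]

    def test_boxes_are_normalized_and_on_canvas(self):
        spec = SceneSpec(n_images=6, image_size=128, rng_seed=5)
        for la, img in generate_scenes(spec):
            assert img.shape == (128, 128, 3) and img.dtype == np.uint8
            for b in la.boxes:
                x1, y1, x2, y2 = b.corners()
                assert 0 <= x1 < x2 <= 1 and 0 <= y1 < y2 <= 1

    def test_class_mix_is_respected(self):
        spec = SceneSpec(n_images=120, image_size=64, rng_seed=1)
        counts = np.zeros(3)
        for la, _ in generate_scenes(spec):
            counts += la.class_counts()
        freq = counts / counts.sum()
        np.testing.assert_allclose(freq, spec.class_mix, atol=0.1)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(class_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SceneSpec(occlusion_prob=1.5)

    def test_save_and_load_round_trip(self, tmp_path):
        spec = SceneSpec(n_images=2, image_size=64, rng_seed=0)
        generate_scenes(spec, out_dir=tmp_path)
        back = load_dataset_dir(tmp_path)
        assert len(back) == 2
        orig = generate_scenes(spec)
        for (lo, io), (lb, ib) in zip(orig, back):
            np.testing.assert_array_equal(io, ib)
            assert len(lo.boxes) == len(lb.boxes)
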