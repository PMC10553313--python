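"""Synthetic planted-patch scenes, augmentations, and the 6:3:1 split."""

import numpy as np
import pytest

from pestnet.attention import box_corners
from pestnet.synthetic import (LabeledImage, SceneSpec, augment,
                               generate_dataset, generate_scene, split_dataset)


class TestGenerateScene:
    def test_degenerate_clutter_is_uniform_outside_patch(self):
        spec = SceneSpec(image_size=32, n_classes=2, patch_half_len_range=(4, 4),
                         clutter_density=0.0, noise_sd=0.0, seed=0)
        im = generate_scene(spec, 0, np.random.default_rng(0))
        b = im.truth_box
        mask = np.ones((32, 32), bool)
        y0, y1 = int(b.ty - b.tl), int(b.ty + b.tl)
        x0, x1 = int(b.tx - b.tl), int(b.tx + b.tl)
        mask[y0:y1 + 1, x0:x1 + 1] = False
        outside = im.pixels[mask]
        assert np.allclose(outside, 0.5, atol=1e-6)

    def test_deterministic_given_seed(self):
        spec = SceneSpec(seed=7)
        a = generate_scene(spec, 1, np.random.default_rng(7))
        b = generate_scene(spec, 1, np.random.default_rng(7))
        assert np.array_equal(a.pixels, b.pixels)
        assert a.truth_box == b.truth_box

    def test_pixels_in_unit_interval_and_box_inside(self, small_spec, rng):
        for c in range(small_spec.n_classes):
            im = generate_scene(small_spec, c, rng)
            assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0
            x0, y0, x1, y1 = box_corners(im.truth_box)
            s = small_spec.image_size
            assert x0 >= -0.5 and y0 >= -0.5 and x1 <= s - 0.5 and y1 <= s - 0.5
            assert im.label == c

    def test_class_id_out_of_range(self, small_spec, rng):
        with pytest.raises(ValueError):
            generate_scene(small_spec, small_spec.n_classes, rng)

    def test_infeasible_patch_range_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(image_size=32, patch_half_len_range=(6, 16))

    def test_signal_is_localized_to_patch(self):
        """Oracle: a multinomial logistic classifier on truth-box crops
        separates the classes (>90% held out), while the same classifier on
        images with the patch blanked out is near chance — the planted
        signal, and only it, is discriminative."""
        from scipy.ndimage import zoom as nd_zoom
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        spec = SceneSpec(seed=11)
        rng_ = np.random.default_rng(11)
        crops, blanks, ys = [], [], []
        for c in range(spec.n_classes):
            for _ in range(50):
                im = generate_scene(spec, c, rng_)
                b = im.truth_box
                y0, y1 = int(b.ty - b.tl), int(b.ty + b.tl) + 1
                x0, x1 = int(b.tx - b.tl), int(b.tx + b.tl) + 1
                crop = im.pixels[y0:y1, x0:x1]
                f = (12 / crop.shape[0], 12 / crop.shape[1], 1)
                crops.append(nd_zoom(crop, f, order=1).ravel())
                blank = im.pixels.copy()
                blank[y0:y1, x0:x1] = 0.5
                blanks.append(blank[::4, ::4].ravel())
                ys.append(c)
        ys = np.array(ys)

        def heldout_acc(features):
            xtr, xte, ytr, yte = train_test_split(
                np.array(features), ys, test_size=0.3, random_state=0,
                stratify=ys)
            clf = LogisticRegression(max_iter=2000).fit(xtr, ytr)
            return clf.score(xte, yte)

        assert heldout_acc(crops) > 0.90
        assert heldout_acc(blanks) < 0.45  # chance is 0.25


class TestAugment:
    def test_empty_ops_is_identity(self, small_dataset, rng):
        im = small_dataset[0]
        out = augment(im, set(), rng)
        assert np.array_equal(out.pixels, im.pixels)
        assert out.truth_box == im.truth_box

    def test_mirror_h_is_involution(self, small_dataset, rng):
        im = small_dataset[0]
        twice = augment(augment(im, {"mirror_h"}, rng), {"mirror_h"}, rng)
        assert np.array_equal(twice.pixels, im.pixels)
        assert twice.truth_box == im.truth_box

    def test_brightness_factor_one_is_identity(self, small_dataset, rng):
        im = small_dataset[0]
        out = augment(im, {"brightness"}, rng, brightness_range=(1.0, 1.0))
        assert np.allclose(out.pixels, im.pixels, atol=1e-7)

    def test_mirror_v_box_arithmetic(self, small_dataset, rng):
        im = small_dataset[0]
        h = im.pixels.shape[0]
        out = augment(im, {"mirror_v"}, rng)
        assert out.truth_box.tx == im.truth_box.tx
        assert out.truth_box.ty == pytest.approx(h - 1 - im.truth_box.ty)
        assert out.truth_box.tl == im.truth_box.tl

    def test_right_angle_rotation_tracks_box(self, small_spec):
        """Plant a bright marker at the box center; after rotation the
        tracked box center must still sit on the marker."""
        rng_ = np.random.default_rng(5)
        im = generate_scene(small_spec, 0, rng_)
        px = im.pixels.copy()
        cy, cx = int(im.truth_box.ty), int(im.truth_box.tx)
        px[cy, cx] = (1.0, 0.0, 1.0)
        marked = LabeledImage(px, im.label, im.truth_box)
        for trial in range(6):
            out = augment(marked, {"rotate"}, np.random.default_rng(trial))
            ny, nx = int(out.truth_box.ty), int(out.truth_box.tx)
            assert tuple(out.pixels[ny, nx]) == (1.0, 0.0, 1.0)

    def test_free_rotation_drops_box(self, small_dataset, rng):
        out = augment(small_dataset[0], {"rotate"}, rng, free_rotation=True)
        assert out.truth_box is None

    def test_label_never_changes(self, small_dataset, rng):
        for im in small_dataset[:5]:
            out = augment(im, {"rotate", "mirror_h", "mirror_v", "brightness"},
                          rng)
            assert out.label == im.label
            assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_unknown_op_rejected(self, small_dataset, rng):
        with pytest.raises(ValueError):
            augment(small_dataset[0], {"sharpen"}, rng)


class TestSplitDataset:
    @staticmethod
    def _fake(n_per_class, n_classes=1):
        out = []
        uid = 0
        for c in range(n_classes):
            for _ in range(n_per_class):
                out.append(LabeledImage(np.zeros((4, 4, 3), np.float32), c,
                                        uid=uid))
                uid += 1
        return out

    def test_631_ratio_single_class(self):
        tr, va, te = split_dataset(self._fake(1000), seed=0)
        assert (len(tr), len(va), len(te)) == (600, 300, 100)

    def test_stratified_counts(self):
        tr, va, te = split_dataset(self._fake(100, n_classes=4), seed=1)
        for c in range(4):
            assert sum(s.label == c for s in tr) == 60
            assert sum(s.label == c for s in va) == 30
            assert sum(s.label == c for s in te) == 10

    def test_partition_property_many_random_inputs(self):
        rng_ = np.random.default_rng(0)
        for _ in range(200):
            n_classes = int(rng_.integers(1, 4))
            sizes = rng_.integers(4, 40, size=n_classes)
            samples = []
            uid = 0
            for c, n in enumerate(sizes):
                for _ in range(n):
                    samples.append(LabeledImage(
                        np.zeros((2, 2, 3), np.float32), c, uid=uid))
                    uid += 1
            if len(samples) < 10:
                continue
            tr, va, te = split_dataset(samples, seed=int(rng_.integers(1e6)))
            ids = sorted(s.uid for s in tr + va + te)
            assert ids == list(range(len(samples)))
            for c, n in enumerate(sizes):
                ntr = sum(s.label == c for s in tr)
                nva = sum(s.label == c for s in va)
                nte = sum(s.label == c for s in te)
                assert abs(ntr - 0.6 * n) <= 1.0001
                assert abs(nva - 0.3 * n) <= 1.0001
                assert abs(nte - 0.1 * n) <= 1.0001

    def test_deterministic_given_seed(self):
        samples = self._fake(30, n_classes=2)
        a = split_dataset(samples, seed=9)
        b = split_dataset(samples, seed=9)
        assert [s.uid for s in a[0]] == [s.uid for s in b[0]]

    def test_small_class_warns(self):
        samples = self._fake(20) + [
            LabeledImage(np.zeros((4, 4, 3), np.float32), 1, uid=99)]
        with pytest.warns(UserWarning):
            split_dataset(samples, seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._fake(5), seed=0)


class TestGenerateDataset:
    def test_split_dict_counts(self, small_spec):
        samples = generate_dataset(small_spec, {"train": 4, "validation": 2,
                                                "test": 1})
        assert len(samples) == small_spec.n_classes * 7
        tags = [s.split_tag for s in samples]
        assert tags.count("train") == small_spec.n_classes * 4
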