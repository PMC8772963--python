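"""Preprocessing chain vs brute-force oracles and phantom ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oracles import brute_largest_component, brute_open
from pemnet.phantom import PhantomSpec, generate_phantom
from pemnet.preprocess import (Mammogram, binarize, crop_to_bbox,
                               detect_orientation, embed_in_frame,
                               extract_breast, flip_to_left, largest_component,
                               morphological_open, normalize_to_8bit)


class TestNormalize:
    def test_constant_grid_maps_to_zero(self):
        assert normalize_to_8bit(np.full((4, 4), 1234)).pixels.max() == 0

    def test_endpoints_and_midpoint(self):
        out = normalize_to_8bit(np.array([[0, 1000, 4095]])).pixels
        np.testing.assert_array_equal(out, [[0, 62, 255]])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_8bit(np.empty((0, 0)))


class TestOrientation:
    def test_left_heavy_and_mirror(self):
        img = np.zeros((10, 10), np.uint8)
        img[:, :4] = 200
        assert detect_orientation(img) == "left"
        assert detect_orientation(img[:, ::-1]) == "right"

    def test_tie_prefers_left(self):
        img = np.zeros((4, 4), np.uint8)
        img[0, 0] = img[0, -1] = 1
        assert detect_orientation(img) == "left"

    def test_phantoms_detected_by_side(self):
        for seed in range(10):
            for side in ("left", "right"):
                ph = generate_phantom(PhantomSpec(seed=seed, side=side))
                assert detect_orientation(ph.image) == side


class TestFlip:
    def test_identity_mirror_involution(self):
        img = np.array([[1, 2], [3, 4]], np.uint8)
        np.testing.assert_array_equal(flip_to_left(img, "left"), img)
        np.testing.assert_array_equal(flip_to_left(img, "right"), [[2, 1], [4, 3]])
        np.testing.assert_array_equal(
            flip_to_left(flip_to_left(img, "right"), "right"), img)


class TestBinarize:
    def test_strict_inequality_at_default_threshold(self):
        out = binarize(np.array([[19, 20, 21]], np.uint8))
        np.testing.assert_array_equal(out, [[False, False, True]])

    def test_constant_zero_empty(self):
        assert not binarize(np.zeros((3, 3), np.uint8)).any()

    def test_threshold_range_checked(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2)), threshold=300)


class TestLargestComponent:
    def test_single_blob_idempotent_and_empty(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        np.testing.assert_array_equal(largest_component(m), m)
        assert not largest_component(np.zeros((4, 4), bool)).any()

    def test_two_blobs_keep_larger(self):
        m = np.zeros((12, 20), bool)
        m[1:6, 1:11] = True     # 50 px
        m[8:11, 1:11] = True    # 30 px
        out = largest_component(m)
        np.testing.assert_array_equal(out, brute_largest_component(m))
        assert out.sum() == 50

    @settings(max_examples=30, deadline=None)
    @given(arrays(bool, (16, 16), elements=st.booleans()),
           st.sampled_from([4, 8]))
    def test_agrees_with_flood_fill(self, mask, conn):
        np.testing.assert_array_equal(largest_component(mask, conn),
                                      brute_largest_component(mask, conn))


class TestOpening:
    def test_radius_zero_identity_and_idempotence(self):
        rng = np.random.default_rng(0)
        m = rng.random((20, 20)) < 0.4
        np.testing.assert_array_equal(morphological_open(m, 0), m)
        once = morphological_open(m, 2)
        np.testing.assert_array_equal(morphological_open(once, 2), once)

    def test_small_disk_removed_large_blob_survives(self):
        m = np.zeros((40, 90), bool)
        rr, cc = np.mgrid[0:40, 0:90]
        m[(rr - 30) ** 2 + (cc - 80) ** 2 <= 4] = True       # radius-2 disk
        m[5:35, 5:65] = True                                 # 60-px-wide blob
        out = morphological_open(m, 3)
        np.testing.assert_array_equal(out, brute_open(m, 3))
        assert not out[25:, 70:].any() and out[10:30, 10:60].all()

    @settings(max_examples=15, deadline=None)
    @given(arrays(bool, (12, 12), elements=st.booleans()),
           st.sampled_from([1, 2]))
    def test_agrees_with_set_morphology(self, mask, radius):
        np.testing.assert_array_equal(morphological_open(mask, radius),
                                      brute_open(mask, radius))


class TestCrop:
    def test_full_frame_and_point(self):
        img = np.arange(12, dtype=np.uint8).reshape(3, 4)
        crop, mask, bbox = crop_to_bbox(img, np.ones((3, 4), bool))
        assert bbox == (0, 0, 3, 4)
        np.testing.assert_array_equal(crop, img)
        m = np.zeros((6, 6), bool)
        m[3, 4] = True
        crop, mask, bbox = crop_to_bbox(img := np.ones((6, 6), np.uint8), m)
        assert bbox == (3, 4, 4, 5) and crop.shape == (1, 1)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError, match="no breast"):
            crop_to_bbox(np.ones((3, 3)), np.zeros((3, 3), bool))


class TestExtractBreast:
    def test_matches_ground_truth_on_clean_phantoms(self, mlo_batch):
        for ph in mlo_batch:
            res = extract_breast(ph.image)
            gt = ph.breast_mask.astype(bool)
            if res.orientation == "right":
                gt = gt[:, ::-1]
            full = embed_in_frame(res, ph.image.shape)
            assert (full & gt).sum() / (full | gt).sum() >= 0.95

    def test_mirror_symmetry_of_chain(self):
        kwargs = dict(seed=3, n_artefacts=2)
        left = generate_phantom(PhantomSpec(side="left", **kwargs))
        right = generate_phantom(PhantomSpec(side="right", **kwargs))
        res_l, res_r = extract_breast(left.image), extract_breast(right.image)
        np.testing.assert_array_equal(res_l.image.pixels, res_r.image.pixels)
        np.testing.assert_array_equal(res_l.breast_mask, res_r.breast_mask)

    def test_margin_artefacts_excluded(self):
        ph = generate_phantom(PhantomSpec(seed=11, n_artefacts=3))
        artefact_pixels = (ph.image > 220) & ~ph.breast_mask.astype(bool)
        assert artefact_pixels.any()
        full = embed_in_frame(extract_breast(ph.image), ph.image.shape)
        assert not (full & artefact_pixels).any()

    def test_never_enlarges(self, mlo_batch):
        for ph in mlo_batch[:5]:
            res = extract_breast(ph.image)
            assert res.image.pixels.size <= ph.image.size
            assert res.breast_mask.shape == res.image.pixels.shape


def test_mammogram_validates_range():
    with pytest.raises(ValueError):
        Mammogram(np.array([[300.0]]))
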