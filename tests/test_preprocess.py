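"""Resize/filter/normalize/augment behaviour and image–mask consistency."""

import numpy as np
import pytest

from gutseg.preprocess import (
    AugmentationPolicy,
    DoubleNormalizationError,
    GrayscaleSlice,
    ShapeConsistencyError,
    augment_pair,
    gaussian_filter_slice,
    normalize,
    normalize_array,
    preprocess_slice,
    resize_pair,
)


class TestResize:
    def test_downscale_to_160(self, rng):
        img = rng.integers(0, 256, (266, 266)).astype(np.uint8)
        mask = (rng.random((266, 266)) < 0.2).astype(np.uint8)
        out_img, out_mask = resize_pair(img, mask, (160, 160))
        assert out_img.shape == (160, 160) and out_mask.shape == (160, 160)
        assert set(np.unique(out_mask)) <= {0, 1}

    def test_identity_resize_is_pixel_identical(self, rng):
        img = rng.integers(0, 256, (160, 160)).astype(np.uint8)
        mask = (rng.random((160, 160)) < 0.2).astype(np.uint8)
        out_img, out_mask = resize_pair(img, mask, (160, 160))
        assert (out_img == img).all() and (out_mask == mask).all()

    def test_constant_mask_invariance(self):
        img = np.zeros((100, 80))
        mask = np.ones((100, 80), np.uint8)
        _, out_mask = resize_pair(img, mask, (160, 160))
        assert out_mask.all()

    def test_mismatched_pair_rejected(self):
        with pytest.raises(ShapeConsistencyError):
            resize_pair(np.zeros((8, 8)), np.zeros((9, 8)), (4, 4))


class TestGaussianFilter:
    def test_preserves_constants(self):
        out = gaussian_filter_slice(np.full((32, 32), 7.0), sigma=1.5)
        assert np.allclose(out, 7.0)

    def test_mass_conserved_for_interior_impulse(self):
        img = np.zeros((33, 33))
        img[16, 16] = 100.0
        out = gaussian_filter_slice(img, sigma=1.0)
        assert np.isclose(out.sum(), 100.0, rtol=1e-6)

    def test_variance_non_increasing_in_sigma(self, rng):
        img = rng.random((64, 64)) * 255
        variances = [gaussian_filter_slice(img, s).var() for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b for a, b in zip(variances, variances[1:]))
        assert variances[0] <= img.var()

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_invalid_sigma(self, sigma):
        with pytest.raises(ValueError):
            gaussian_filter_slice(np.zeros((4, 4)), sigma)


class TestNormalize:
    @pytest.mark.parametrize("value, expected", [(255, 1.0), (0, 0.0), (51, 0.2)])
    def test_divide_by_255(self, value, expected):
        out = normalize(GrayscaleSlice(np.full((2, 2), value, dtype=np.uint16)))
        assert np.allclose(out.pixels, expected)
        assert out.value_domain == "unit"

    def test_16bit_rescaled_first(self):
        out = normalize(GrayscaleSlice(np.full((2, 2), 65535, dtype=np.uint16)))
        assert np.allclose(out.pixels, 1.0)

    def test_double_normalization_guard(self):
        once = normalize(GrayscaleSlice(np.full((2, 2), 128, np.uint8)))
        with pytest.raises(DoubleNormalizationError):
            normalize(once)

    def test_array_helper_range(self, rng):
        out = normalize_array(rng.integers(0, 256, (8, 8)).astype(np.uint8))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestAugment:
    def test_fixed_seed_byte_identical(self, rng):
        img = rng.random((48, 48))
        mask = (rng.random((48, 48)) < 0.2).astype(np.uint8)
        pol = AugmentationPolicy()
        a1 = augment_pair(img, mask, pol, np.random.default_rng(5))
        a2 = augment_pair(img, mask, pol, np.random.default_rng(5))
        assert (a1[0] == a2[0]).all() and (a1[1] == a2[1]).all()

    def test_flip_is_involution(self, rng):
        img = rng.random((16, 16))
        mask = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        pol = AugmentationPolicy(horizontal_flip_prob=1.0, rotation_limit=0.0, zoom_fraction=0.0)
        g = np.random.default_rng(0)
        once = augment_pair(img, mask, pol, g)
        twice = augment_pair(once[0], once[1], pol, g)
        assert np.allclose(twice[0], img) and (twice[1] == mask).all()

    def test_rotated_disk_area_conserved(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 14**2).astype(np.uint8)
        pol = AugmentationPolicy(horizontal_flip_prob=0.0, rotation_limit=120.0, zoom_fraction=0.0)
        for seed in range(5):
            _, out = augment_pair(disk.astype(float), disk, pol, np.random.default_rng(seed))
            assert abs(int(out.sum()) - int(disk.sum())) / int(disk.sum()) < 0.02

    def test_landmark_stays_locked(self):
        """A pixel marked in both image and mask lands on the same spot."""
        img = np.zeros((64, 64))
        mask = np.zeros((64, 64), np.uint8)
        img[40, 22] = 1.0
        mask[40, 22] = 1
        pol = AugmentationPolicy(seed=0)
        for seed in range(6):
            oi, om = augment_pair(img, mask, pol, np.random.default_rng(seed))
            if om.sum() == 0:  # landmark may leave the frame under zoom-out crop
                continue
            img_pos = np.unravel_index(np.argmax(oi), oi.shape)
            mask_pos = np.argwhere(om == 1)
            assert (np.abs(np.asarray(img_pos) - mask_pos).sum(axis=1) <= 1).any()

    def test_shapes_unchanged(self, rng):
        img = rng.random((40, 40))
        mask = (rng.random((40, 40)) < 0.2).astype(np.uint8)
        oi, om = augment_pair(img, mask, AugmentationPolicy(), np.random.default_rng(3))
        assert oi.shape == (40, 40) and om.shape == (40, 40)


def test_pipeline_order_and_idempotence_guard(rng):
    raw = rng.integers(0, 256, (100, 100)).astype(np.uint8)
    mask = (rng.random((100, 100)) < 0.2).astype(np.uint8)
    out, msk = preprocess_slice(GrayscaleSlice(raw, "s1"), mask, (64, 64), sigma=1.0)
    assert out.pixels.shape == (64, 64) and msk.shape == (64, 64)
    assert 0.0 <= out.pixels.min() and out.pixels.max() <= 1.0
    with pytest.raises(DoubleNormalizationError):
        normalize(out)
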