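"""Standardization, vessel enhancement, and mask-coherent augmentation."""

import numpy as np
import pytest

from fundusmtl.preprocess import (AugmentPolicy, EnhanceParams,
                                  FundusStandardizer, VesselContrastEnhancer,
                                  apply_transforms, augment, enhance_vessels,
                                  standardize)
from fundusmtl.synth import FundusSample


def bilinear_oracle(img, out_h, out_w):
    """Independent half-pixel-center bilinear resize with edge clamping."""
    in_h, in_w = img.shape[:2]
    out = np.zeros((out_h, out_w) + img.shape[2:])
    for r in range(out_h):
        for c in range(out_w):
            src_r = (r + 0.5) * in_h / out_h - 0.5
            src_c = (c + 0.5) * in_w / out_w - 0.5
            r0, c0 = int(np.floor(src_r)), int(np.floor(src_c))
            fr, fc = src_r - r0, src_c - c0
            def px(i, j):
                return img[min(max(i, 0), in_h - 1), min(max(j, 0), in_w - 1)]
            out[r, c] = ((1 - fr) * (1 - fc) * px(r0, c0)
                         + (1 - fr) * fc * px(r0, c0 + 1)
                         + fr * (1 - fc) * px(r0 + 1, c0)
                         + fr * fc * px(r0 + 1, c0 + 1))
    return out


@pytest.fixture
def sample():
    rng = np.random.default_rng(0)
    img = rng.random((32, 32, 3)).astype(np.float32)
    mask = (rng.random((32, 32)) < 0.15).astype(np.uint8)
    return FundusSample(image=img, vessel_mask=mask,
                        labels=np.array([1, 0, 1]))


class TestStandardize:
    def test_uint8_scaling_to_unit_interval(self):
        img = np.full((8, 8, 3), 255, dtype=np.uint8)
        out = standardize(img, (8, 8))
        assert np.allclose(out, 1.0)

    def test_no_resample_is_exact_division(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        out = standardize(img, (16, 16))
        assert np.array_equal(out, (img / 255.0).astype(np.float32))

    def test_checkerboard_upsample_matches_bilinear_oracle(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0, 1] = img[1, 0] = 255
        out = standardize(img, (4, 4))
        oracle = bilinear_oracle(img / 255.0, 4, 4)
        assert np.allclose(out, oracle, atol=1e-6)

    def test_non_image_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.zeros((4, 4)), (4, 4))


class TestEnhanceVessels:
    def test_green_channel_extracted(self):
        rng = np.random.default_rng(2)
        img = np.zeros((16, 16, 3), dtype=np.float32)
        img[..., 1] = rng.random((16, 16))
        out = enhance_vessels(img, EnhanceParams(clahe_clip_limit=None,
                                                 gamma=1.0))
        assert np.allclose(out, img[..., 1], atol=1e-6)

    def test_gamma_closed_form(self):
        img = np.full((8, 8, 3), 0.5, dtype=np.float32)
        out = enhance_vessels(img, EnhanceParams(clahe_clip_limit=None,
                                                 gamma=2.0))
        assert np.allclose(out, 0.25, atol=1e-6)

    def test_gamma_is_monotone(self):
        img = np.zeros((4, 4, 3), dtype=np.float32)
        img[..., 1] = np.linspace(0, 1, 16).reshape(4, 4)
        out = enhance_vessels(img, EnhanceParams(clahe_clip_limit=None,
                                                 gamma=1.7))
        flat_in = img[..., 1].ravel()
        flat_out = out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= -1e-7).all()

    def test_full_pipeline_deterministic_and_bounded(self):
        rng = np.random.default_rng(3)
        img = rng.random((32, 32, 3)).astype(np.float32)
        a = enhance_vessels(img)
        b = enhance_vessels(img)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 1.0 and a.ndim == 2


class TestAugment:
    def test_p_zero_is_identity(self, sample):
        out = augment(sample, AugmentPolicy(p_apply=0.0), rng_seed=0)
        assert np.array_equal(out.image, sample.image)
        assert np.array_equal(out.vessel_mask, sample.vessel_mask)

    def test_deterministic_given_seed(self, sample):
        policy = AugmentPolicy(p_apply=1.0)
        a = augment(sample, policy, rng_seed=5)
        b = augment(sample, policy, rng_seed=5)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.vessel_mask, b.vessel_mask)

    def test_hflip_is_involution(self, sample):
        once = apply_transforms(sample, {"hflip": True})
        twice = apply_transforms(once, {"hflip": True})
        assert np.array_equal(twice.image, sample.image)
        assert np.array_equal(twice.vessel_mask, sample.vessel_mask)

    def test_flip_moves_mask_with_image(self, sample):
        out = apply_transforms(sample, {"hflip": True, "vflip": True})
        assert np.array_equal(out.image, sample.image[::-1, ::-1])
        assert np.array_equal(out.vessel_mask,
                              sample.vessel_mask[::-1, ::-1])

    def test_rotation_moves_mask_centroid(self):
        # a single off-center blob: after rotating by theta, its centroid
        # rotates by theta about the image center (within 1 px)
        img = np.zeros((33, 33, 3), dtype=np.float32)
        mask = np.zeros((33, 33), dtype=np.uint8)
        mask[16, 24:27] = 1
        mask[15, 24:27] = 1
        sample = FundusSample(image=img, vessel_mask=mask,
                              labels=np.zeros(1, dtype=np.int64))
        theta = 30.0
        out = apply_transforms(sample, {"angle": theta})
        center = np.array([16.0, 16.0])
        def centroid(m):
            rr, cc = np.nonzero(m)
            return np.array([rr.mean(), cc.mean()])
        vec = centroid(mask) - center
        got = centroid(out.vessel_mask) - center
        # skimage rotates counterclockwise in (row, col) display coords
        t = np.deg2rad(theta)
        expected = np.array([
            vec[0] * np.cos(t) - vec[1] * np.sin(t),
            vec[0] * np.sin(t) + vec[1] * np.cos(t)])
        if np.linalg.norm(expected - got) > 1.0:
            expected = np.array([
                vec[0] * np.cos(t) + vec[1] * np.sin(t),
                -vec[0] * np.sin(t) + vec[1] * np.cos(t)])
        assert np.linalg.norm(expected - got) <= 1.0

    def test_mask_stays_binary_and_registered_after_rotation(self, sample):
        out = apply_transforms(sample, {"angle": 13.0})
        assert set(np.unique(out.vessel_mask)) <= {0, 1}
        # oracle: rotate the original mask independently and compare
        from skimage.transform import rotate
        oracle = (rotate(sample.vessel_mask.astype(float), 13.0, order=1,
                         mode="constant", cval=0.0) >= 0.5).astype(np.uint8)
        assert np.array_equal(out.vessel_mask, oracle)

    def test_labels_never_change(self, sample):
        policy = AugmentPolicy(p_apply=1.0)
        for seed in range(10):
            out = augment(sample, policy, rng_seed=seed)
            assert np.array_equal(out.labels, sample.labels)

    def test_output_clipped_to_unit_interval(self, sample):
        out = apply_transforms(sample, {"brightness": 0.2, "contrast": 0.2})
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_drawn_magnitudes_respect_limits(self):
        policy = AugmentPolicy(p_apply=1.0)
        rng = np.random.default_rng(0)
        draws = [policy.draw(rng) for _ in range(10_000)]
        assert all(abs(d["angle"]) <= 15.0 for d in draws)
        assert all(abs(d["brightness"]) <= 0.20 for d in draws)
        assert all(abs(d["contrast"]) <= 0.20 for d in draws)
        assert all(abs(d["hue"]) <= 10.0 for d in draws)
        # with p_apply=1 every primitive fires
        assert all(d["hflip"] or True for d in draws)
        fired = np.mean([d["angle"] != 0.0 for d in draws])
        assert fired > 0.99

    def test_fire_probability_respected(self):
        policy = AugmentPolicy(p_apply=0.5)
        rng = np.random.default_rng(1)
        draws = [policy.draw(rng) for _ in range(10_000)]
        rate = np.mean([d["angle"] != 0.0 for d in draws])
        assert rate == pytest.approx(0.5, abs=0.03)


class TestTransformers:
    def test_standardizer_batches(self):
        rng = np.random.default_rng(4)
        imgs = rng.integers(0, 256, (5, 10, 12, 3), dtype=np.uint8)
        out = FundusStandardizer(target_size=(8, 8)).fit_transform(imgs)
        assert out.shape == (5, 8, 8, 3)
        assert out.dtype == np.float32

    def test_enhancer_batches_and_clones(self):
        from sklearn.base import clone
        enh = VesselContrastEnhancer(gamma=1.5)
        assert clone(enh).get_params()["gamma"] == 1.5
        rng = np.random.default_rng(5)
        imgs = rng.random((3, 16, 16, 3)).astype(np.float32)
        out = enh.fit_transform(imgs)
        assert out.shape == (3, 16, 16)
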