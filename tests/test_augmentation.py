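"""Augmentation protocol: noise moments, Retinex properties, rotation
bounds, text variants, and dataset expansion accounting."""

import numpy as np
import pytest
from scipy import ndimage

from cropvqa.augmentation import (AugmentationPlan, add_gaussian_noise,
                                  sample_noise_field,
                                  augment_text, expand_dataset, msrcp, msrcr,
                                  random_rotate, rotate_image,
                                  single_scale_retinex)
from cropvqa.dataset_io import VQATriple
from cropvqa.errors import ConfigError, InputError


@pytest.fixture()
def plan():
    return AugmentationPlan(seed=42)


def random_image(seed, shape=(32, 32, 3)):
    return np.random.default_rng(seed).random(shape)


class TestGaussianNoise:
    def test_zero_variance_is_identity(self):
        img = random_image(0)
        out = add_gaussian_noise(img, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, img)

    @pytest.mark.parametrize("variance", [0.1, 0.01])
    def test_moments_on_interior_gray_within_3_sigma(self, variance):
        """Sample mean ~ 0 and sample variance ~ sigma^2 at 1e5 pixels of
        the raw noise field (clipping truncates the displayed tails)."""
        n = 100_000
        rng = np.random.default_rng(7)
        noise = sample_noise_field((250, 400), variance, rng).ravel()
        se_mean = np.sqrt(variance / n)
        assert abs(noise.mean()) < 3 * se_mean
        se_var = variance * np.sqrt(2.0 / (n - 1))
        assert abs(noise.var() - variance) < 3 * se_var

    def test_default_plan_exposes_protocol_variances(self, plan):
        assert plan.noise_variances == [0.1, 0.01]

    def test_negative_variance_rejected(self):
        with pytest.raises(InputError):
            add_gaussian_noise(random_image(1), -0.1, np.random.default_rng(0))


class TestRetinex:
    def test_constant_image_gives_zero_log_ratio(self):
        img = np.full((16, 16, 3), 0.3)
        out = single_scale_retinex(img, scale=3.0)
        assert np.abs(out).max() < 1e-9

    def test_invariant_to_global_intensity_scaling(self):
        img = 0.2 + 0.6 * random_image(2, (16, 16, 3))
        a = single_scale_retinex(img, 2.0)
        b = single_scale_retinex(0.5 * img, 2.0)
        assert np.abs(a - b).max() < 1e-9

    def test_matches_spatial_convolution_oracle(self):
        """Gaussian surround via an explicit kernel correlation on a 16x16
        single-channel input."""
        img = 0.1 + 0.8 * random_image(3, (16, 16))
        sigma = 2.0
        out = single_scale_retinex(img, sigma)
        radius = int(4.0 * sigma + 0.5)
        x = np.arange(-radius, radius + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        blur = ndimage.correlate(img, kernel, mode="nearest")
        oracle = np.log(img) - np.log(blur)
        assert np.abs(out - oracle).max() < 1e-7

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(InputError):
            single_scale_retinex(random_image(4), 0.0)


class TestMSRCR:
    def test_constant_gray_maps_to_constant(self, plan):
        img = np.full((24, 24, 3), 0.5)
        out = msrcr(img, plan)
        assert out.shape == img.shape
        assert np.abs(out - out[0, 0]).max() < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_output_range_within_unit_interval(self, seed, plan):
        out = msrcr(random_image(seed, (24, 24, 3)), plan)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_compresses_dynamic_range_of_half_dark_half_bright(self, plan):
        img = np.full((32, 32, 3), 0.05)
        img[:, 16:] = 0.9
        out = msrcr(img, plan)
        eps = 1e-6
        before = img[:, 16:].mean() / (img[:, :16].mean() + eps)
        after = (out[:, 16:].mean() + eps) / (out[:, :16].mean() + eps)
        assert after < before


class TestMSRCP:
    @pytest.mark.parametrize("seed", range(3))
    def test_chromaticity_preserved_per_pixel(self, seed, plan):
        img = 0.1 + 0.8 * random_image(seed, (24, 24, 3))
        out = msrcp(img, plan)
        ratios_in = img / img.sum(axis=2, keepdims=True)
        sums = out.sum(axis=2, keepdims=True)
        nonzero = sums[:, :, 0] > 1e-9
        ratios_out = out[nonzero] / sums[nonzero]
        assert np.abs(ratios_out - ratios_in[nonzero]).max() < 1e-3

    def test_grayscale_input_stays_grayscale(self, plan):
        gray = random_image(5, (24, 24))
        img = np.repeat(gray[:, :, None], 3, axis=2)
        out = msrcp(img, plan)
        assert np.abs(out - out.mean(axis=2, keepdims=True)).max() < 1e-9

    def test_constant_image_is_fixed_point_up_to_gain(self, plan):
        img = np.full((24, 24, 3), 0.4)
        out = msrcp(img, plan)
        ratio = out / img
        assert np.abs(ratio - ratio[0, 0]).max() < 1e-6


class TestRotation:
    def test_angles_always_within_range(self, plan):
        rng = np.random.default_rng(0)
        lo, hi = plan.rotation_range
        angles = [random_rotate(np.zeros((4, 4, 3)), plan, rng)[1]
                  for _ in range(10_000)]
        assert min(angles) >= lo and max(angles) <= hi

    def test_seeded_rng_reproduces_angle_sequence(self, plan):
        a1 = [random_rotate(np.zeros((4, 4, 3)), plan,
                            np.random.default_rng(9))[1] for _ in range(1)]
        a2 = [random_rotate(np.zeros((4, 4, 3)), plan,
                            np.random.default_rng(9))[1] for _ in range(1)]
        assert a1 == a2

    def test_90_degree_rotation_transposes_axis_aligned_bar(self):
        img = np.zeros((33, 33, 3))
        img[16, 4:29] = 1.0  # horizontal bar
        out = rotate_image(img, 90.0)
        col_mass = out[:, 16].sum()
        row_mass = out[16, :].sum()
        assert col_mass > 0.8 * img.sum() / 3
        assert out[4:29, 16].mean() > out[4:29, 10].mean()
        assert row_mass < col_mass

    def test_rotation_keeps_unit_range(self, plan):
        out, _ = random_rotate(random_image(6), plan, np.random.default_rng(1))
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestTextAugmentation:
    def test_lowercase_is_idempotent(self):
        v1 = augment_text("What COLOR is the Spot?")
        lowered = [s for s in v1 if s == s.lower()]
        assert lowered
        assert augment_text(lowered[0])[0] == lowered[0]

    def test_punctuation_removal_keeps_at_least_one_token(self):
        variants = augment_text("diseased?!")
        for v in variants:
            assert len(v.split()) >= 1

    def test_synonym_substitution_is_table_driven(self):
        table = {"spot": "lesion", "fruit": "crop"}
        variants = augment_text("what color is the spot?", table,
                                np.random.default_rng(0))
        assert any("lesion" in v for v in variants)

    def test_empty_synonym_table_rejected(self):
        with pytest.raises(ConfigError):
            augment_text("what color is the spot?", {})

    def test_empty_question_rejected(self):
        with pytest.raises(InputError):
            augment_text("   ")


def _mini_triples():
    answers = [("yes", "yes")] * 10
    return [VQATriple(image_id=f"i{j}", question_id=f"q{j}",
                      question="Is the fruit diseased?", answers=answers,
                      question_category="yes/no") for j in range(2)]


class TestExpandDataset:
    def test_all_ops_off_is_identity(self):
        plan = AugmentationPlan(enable_noise=False, enable_msrcr=False,
                                enable_msrcp=False, enable_rotation=False,
                                enable_text_ops=False, seed=0)
        triples = _mini_triples()
        images = {f"i{j}": random_image(j) for j in range(2)}
        out_t, out_i, prov = expand_dataset(triples, images, plan)
        assert out_t == triples and out_i.keys() == images.keys()
        assert prov == []

    def test_image_count_multiplied_by_one_plus_k_ops(self):
        plan = AugmentationPlan(enable_text_ops=False, seed=1)
        k = len(plan.enabled_image_ops())  # 2 noise + msrcr + msrcp + rotate
        assert k == 5
        triples = _mini_triples()
        images = {f"i{j}": random_image(j) for j in range(2)}
        out_t, out_i, _ = expand_dataset(triples, images, plan)
        assert len(out_i) == len(images) * (1 + k)
        assert len(out_t) == len(triples) * (1 + k)

    def test_derived_records_have_fresh_ids_and_same_labels(self):
        plan = AugmentationPlan(enable_msrcr=False, enable_msrcp=False,
                                enable_rotation=False, enable_text_ops=False,
                                seed=2)
        triples = _mini_triples()
        images = {f"i{j}": random_image(j) for j in range(2)}
        out_t, _, prov = expand_dataset(triples, images, plan)
        ids = [t.question_id for t in out_t]
        assert len(set(ids)) == len(ids)
        for t in out_t:
            assert t.answers == triples[0].answers
        assert all(p["question_id"] != p["source_question"] for p in prov)

    def test_expansion_deterministic_under_fixed_seed(self):
        plan = AugmentationPlan(seed=3)
        triples = _mini_triples()
        images = {f"i{j}": random_image(j) for j in range(2)}
        _, i1, _ = expand_dataset(triples, images, plan)
        _, i2, _ = expand_dataset(triples, images, plan)
        for key in i1:
            assert np.array_equal(i1[key], i2[key])

    def test_oversampling_equalizes_category_counts(self):
        plan = AugmentationPlan(enable_noise=False, enable_msrcr=False,
                                enable_msrcp=False, enable_rotation=False,
                                enable_text_ops=False,
                                oversample_categories=True, seed=4)
        answers = [("3", "yes")] * 10
        triples = _mini_triples() + [
            VQATriple(image_id="i9", question_id="qn", answers=answers,
                      question="how many spots?", question_category="number")]
        images = {t.image_id: random_image(0) for t in triples}
        out_t, _, _ = expand_dataset(triples, images, plan)
        from collections import Counter
        counts = Counter(t.question_category for t in out_t)
        assert counts["number"] == counts["yes/no"]
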