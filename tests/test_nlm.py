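import math

import numpy as np
import pytest

from mrordenoise import (
    NLMConfig,
    NoiseSpec,
    corrupt,
    denoise,
    detect_full,
    nlm_restore,
    patch_distance,
    psnr,
    standard_median,
)


def no_flags(shape):
    return np.zeros(shape, dtype=bool)


class TestPatchDistance:
    def test_self_distance_zero(self, phantom_128):
        cfg = NLMConfig()
        mask = no_flags(phantom_128.shape)
        assert patch_distance(phantom_128, mask, (40, 40), (40, 40), cfg) == 0.0

    def test_constant_patches_zero(self, flat_image):
        assert patch_distance(flat_image, no_flags(flat_image.shape), (5, 5), (20, 20)) == 0.0

    def test_single_pixel_patches(self):
        img = np.full((16, 16), 10.0)
        img[8, 8] = 16.0
        cfg = NLMConfig(patch_radius=0, search_radius=5)
        assert patch_distance(img, no_flags(img.shape), (4, 4), (8, 8), cfg) == 36.0

    def test_masked_positions_ignored(self):
        img = np.full((16, 16), 10.0)
        img[4, 4] = 250.0  # corrupted, must not enter the distance
        mask = no_flags(img.shape)
        mask[4, 4] = True
        d = patch_distance(img, mask, (4, 4), (10, 10), NLMConfig(patch_radius=1))
        assert d == 0.0

    def test_incomparable_sentinel_when_overlap_too_small(self):
        img = np.full((16, 16), 10.0)
        mask = np.ones(img.shape, dtype=bool)
        mask[0, :] = False
        d = patch_distance(img, mask, (8, 8), (10, 10), NLMConfig(patch_radius=2))
        assert math.isinf(d)


class TestNlmRestore:
    def test_empty_mask_identity(self, phantom_128):
        ref = phantom_128.copy()
        out = nlm_restore(phantom_128, no_flags(phantom_128.shape), ref)
        assert np.array_equal(out, phantom_128)

    def test_constant_reference_restores_constant(self):
        img = np.full((32, 32), 70.0)
        img[16, 16] = 255.0
        mask = no_flags(img.shape)
        mask[16, 16] = True
        out = nlm_restore(img, mask, np.full((32, 32), 70.0))
        assert out[16, 16] == pytest.approx(70.0)

    def test_two_region_phantom_respects_region(self):
        ref = np.full((32, 32), 40.0)
        ref[:, 16:] = 160.0
        img = ref.copy()
        img[16, 8] = 255.0
        mask = no_flags(img.shape)
        mask[16, 8] = True
        out = nlm_restore(img, mask, ref)
        assert out[16, 8] == pytest.approx(40.0, abs=1.0)

    def test_unflagged_pixels_bit_identical(self, phantom_128):
        noisy, _ = corrupt(phantom_128, NoiseSpec(kind="random_valued", p=0.2, seed=3))
        result = detect_full(noisy)
        out = nlm_restore(noisy, result.mask, result.restored)
        assert np.array_equal(out[~result.mask], noisy[~result.mask])

    def test_restored_values_convex_in_reference_range(self, phantom_128):
        noisy, _ = corrupt(phantom_128, NoiseSpec(kind="fixed_valued", p=0.3, seed=6))
        result = detect_full(noisy)
        out = nlm_restore(noisy, result.mask, result.restored)
        lo, hi = result.restored.min(), result.restored.max()
        assert out[result.mask].min() >= lo - 1e-9
        assert out[result.mask].max() <= hi + 1e-9

    def test_infinite_bandwidth_matches_clean_candidate_mean(self):
        """h -> inf limit: unweighted mean over comparable clean candidates."""
        rng = np.random.default_rng(7)
        ref = np.floor(rng.uniform(0, 256, (32, 32))).clip(0, 255)
        img = ref.copy()
        img[15, 15] = 0.0
        mask = no_flags(ref.shape)
        mask[15, 15] = True
        cfg = NLMConfig(patch_radius=2, search_radius=4, bandwidth_h=1e8)
        out = nlm_restore(img, mask, ref, cfg)
        # independent expectation via the pairwise distance function
        cands = []
        for dy in range(-4, 5):
            for dx in range(-4, 5):
                q = (15 + dy, 15 + dx)
                if mask[q]:
                    continue
                if math.isfinite(patch_distance(ref, mask, (15, 15), q, cfg)):
                    cands.append(ref[q])
        assert out[15, 15] == pytest.approx(np.mean(cands), abs=1e-6)

    def test_vectorized_weights_match_pairwise_definition(self):
        """The swept implementation equals a direct per-candidate loop."""
        rng = np.random.default_rng(11)
        ref = np.floor(rng.uniform(0, 256, (24, 24))).clip(0, 255)
        img = ref.copy()
        mask = rng.random(ref.shape) < 0.15
        mask[12, 12] = True
        cfg = NLMConfig(patch_radius=2, search_radius=3, bandwidth_h=15.0)
        out = nlm_restore(img, mask, ref, cfg)
        num = den = 0.0
        for dy in range(-3, 4):
            for dx in range(-3, 4):
                q = (12 + dy, 12 + dx)
                if mask[q]:
                    continue
                d = patch_distance(ref, mask, (12, 12), q, cfg)
                if math.isinf(d):
                    continue
                w = math.exp(-d / cfg.bandwidth_h**2)
                num += w * ref[q]
                den += w
        assert out[12, 12] == pytest.approx(num / den, abs=1e-6)


class TestDenoisePipeline:
    def test_clean_constant_image_unchanged(self, flat_image):
        assert np.array_equal(denoise(flat_image), flat_image)

    def test_denoising_improves_psnr_at_10pct(self, phantom_128):
        noisy, _ = corrupt(phantom_128, NoiseSpec(kind="random_valued", p=0.1, seed=0))
        assert psnr(phantom_128, denoise(noisy)) > psnr(phantom_128, noisy)

    def test_beats_standard_median_at_30pct(self, phantom_128):
        noisy, _ = corrupt(phantom_128, NoiseSpec(kind="random_valued", p=0.3, seed=0))
        assert psnr(phantom_128, denoise(noisy)) > psnr(
            phantom_128, standard_median(noisy)
        )

    def test_pipeline_deterministic(self, phantom_128):
        noisy, _ = corrupt(phantom_128, NoiseSpec(kind="fixed_valued", p=0.1, seed=9))
        assert np.array_equal(denoise(noisy), denoise(noisy))

    @pytest.mark.parametrize(
        "bad", [dict(bandwidth_h=0), dict(search_radius=1, patch_radius=3),
                dict(min_clean_fraction=0.0)]
    )
    def test_invalid_config(self, bad):
        with pytest.raises(ValueError):
            NLMConfig(**bad).validate()
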