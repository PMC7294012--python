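import numpy as np
import pytest

from mrordenoise import (
    DetectionConfig,
    NoiseSpec,
    corrupt,
    decide_cluster,
    detect,
    detect_coarse,
    detect_fine,
    detect_full,
    detection_scores,
)


class TestDecideCluster:
    def test_rule_evaluates_per_cluster_threshold(self):
        img = np.full((16, 16), 50.0)
        img[3, 3] = 255.0  # deviation 205 in cluster 1, threshold 45
        img[5, 5] = 60.0  # deviation 10 in cluster 4, threshold 15
        amed = np.full((16, 16), 50.0)
        cmap = np.full((16, 16), 4, dtype=np.int8)
        cmap[3, 3] = 1
        mask = decide_cluster(img, amed, cmap, (45, 30, 20, 15))
        assert mask[3, 3] and not mask[5, 5]
        assert mask.sum() == 1

    def test_constant_image_never_flags(self, flat_image):
        amed = flat_image.copy()
        cmap = np.full(flat_image.shape, 4, dtype=np.int8)
        assert not decide_cluster(flat_image, amed, cmap, (45, 30, 20, 15)).any()

    def test_shape_mismatch_rejected(self, flat_image):
        with pytest.raises(ValueError, match="shape"):
            decide_cluster(flat_image, flat_image[:16], flat_image, (1, 1, 1, 1))


class TestCoarseStage:
    def test_clean_constant_image_untouched(self, flat_image):
        mask, restored = detect_coarse(flat_image)
        assert not mask.any()
        assert np.array_equal(restored, flat_image)

    def test_isolated_impulses_caught_in_first_iteration(self):
        img = np.full((32, 32), 50.0)
        spots = [(5, 5), (5, 25), (16, 16), (25, 5), (25, 25)]
        for r, c in spots:
            img[r, c] = 255.0
        result = detect_full(img)
        assert result.coarse_new_flags[0] == 5
        assert sum(result.coarse_new_flags[1:]) == 0
        assert {tuple(rc) for rc in np.argwhere(result.mask)} == set(spots)

    def test_mask_never_shrinks_with_more_iterations(self, noisy_pair):
        noisy, _ = noisy_pair
        m1, _ = detect_coarse(noisy, DetectionConfig(coarse_iterations=1))
        m4, _ = detect_coarse(noisy, DetectionConfig(coarse_iterations=4))
        assert (m1 <= m4).all()


class TestFineStage:
    def test_empty_prior_on_constant_image(self, flat_image):
        prior = np.zeros(flat_image.shape, dtype=bool)
        assert not detect_fine(flat_image, prior, DetectionConfig()).any()

    def test_output_contains_prior(self, noisy_pair):
        noisy, _ = noisy_pair
        prior_mask, restored = detect_coarse(noisy)
        final = detect_fine(restored, prior_mask, DetectionConfig())
        assert (prior_mask <= final).all()

    def test_low_amplitude_impulse_caught_only_by_fine_threshold(self):
        img = np.full((32, 32), 50.0)
        img[16, 16] = 70.0  # amplitude 20
        cfg = DetectionConfig(
            coarse_thresholds=(45.0,) * 4, fine_thresholds=(12.0,) * 4
        )
        coarse_mask, restored = detect_coarse(img, cfg)
        assert not coarse_mask.any()
        final = detect_fine(restored, coarse_mask, cfg)
        assert final[16, 16] and final.sum() == 1


class TestFullCascade:
    def test_switching_contract(self, phantom_128, noisy_pair):
        """Never-flagged pixels survive the whole pipeline bit-identically."""
        from mrordenoise import denoise, detect

        noisy, _ = noisy_pair
        mask = detect(noisy)
        out = denoise(noisy)
        assert np.array_equal(out[~mask], noisy[~mask])

    def test_final_mask_contains_coarse_mask(self, noisy_pair):
        noisy, _ = noisy_pair
        coarse_mask, _ = detect_coarse(noisy)
        assert (coarse_mask <= detect(noisy)).all()

    def test_raising_thresholds_never_enlarges_mask(self, phantom_128):
        noisy, _ = corrupt(phantom_128, NoiseSpec(kind="random_valued", p=0.2, seed=2))
        base = DetectionConfig()
        raised = DetectionConfig(
            coarse_thresholds=tuple(1.5 * t for t in base.coarse_thresholds),
            fine_thresholds=tuple(1.5 * t for t in base.fine_thresholds),
        )
        assert (detect(noisy, raised) <= detect(noisy, base)).all()

    def test_cascade_beats_single_coarse_pass(self, phantom_128):
        noisy, truth = corrupt(phantom_128, NoiseSpec(kind="random_valued", p=0.2, seed=4))
        single = DetectionConfig(coarse_iterations=1, fine_iterations=1,
                                 fine_thresholds=(44.9, 29.9, 19.9, 14.9))
        rec_single, _ = detection_scores(truth, detect_coarse(noisy, single)[0])
        rec_full, _ = detection_scores(truth, detect(noisy))
        assert rec_full > rec_single

    def test_recall_non_decreasing_in_impulse_amplitude(self):
        img = np.full((32, 32), 100.0)
        recalls = []
        for amp in (20.0, 60.0, 120.0):
            noisy = img.copy()
            truth = np.zeros(img.shape, dtype=bool)
            rng = np.random.default_rng(0)
            idx = rng.choice(img.size, 60, replace=False)
            truth.ravel()[idx] = True
            noisy[truth] = 100.0 + amp
            rec, _ = detection_scores(truth, detect(noisy))
            recalls.append(rec)
        assert recalls == sorted(recalls)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(coarse_iterations=0),
            dict(fine_thresholds=(50.0, 18.0, 12.0, 8.0)),  # not below coarse
            dict(coarse_thresholds=(45.0, 30.0, 20.0)),
        ],
    )
    def test_invalid_config(self, bad):
        with pytest.raises(ValueError):
            DetectionConfig(**bad).validate()
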