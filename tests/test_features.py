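"""Feature extraction: texture/shape/intensity blocks, deep features,
standardization, sigmoid gating and 176-dim fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arlnet import models
from arlnet.features import (FeatureScaler, FusedFeaturePipeline, N_FUSED,
                             attention_gate_deep, extract_deep_features,
                             fit_attention_gate, fuse_features, glcm_features,
                             handcrafted_features, intensity_features,
                             lbp_codes, lbp_features, shape_features)


def brute_force_glcm_props(img: np.ndarray, levels: int, offset: tuple[int, int]):
    """Independent oracle: exhaustive symmetric co-occurrence counting
    for one pixel-pair offset, then the textbook property formulas."""
    q = np.clip((img * levels).astype(int), 0, levels - 1)
    counts = np.zeros((levels, levels))
    h, w = q.shape
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1  # symmetric
    p = counts / counts.sum()
    i, j = np.mgrid[0:levels, 0:levels]
    contrast = (p * (i - j) ** 2).sum()
    dissim = (p * np.abs(i - j)).sum()
    homog = (p / (1 + (i - j) ** 2)).sum()
    energy = np.sqrt((p ** 2).sum())
    return contrast, dissim, homog, energy


class TestGLCM:
    def test_length_is_15(self):
        assert len(glcm_features(np.random.default_rng(0).random((16, 16)))) == 15

    def test_constant_image_degenerate_values(self):
        feats = glcm_features(np.full((12, 12), 0.4))
        for a in range(3):
            contrast, dissim, homog, energy, corr = feats[5 * a:5 * a + 5]
            assert contrast == 0 and dissim == 0
            assert homog == 1 and energy == 1
            assert corr == 1  # perfectly self-similar by convention

    def test_horizontal_props_match_bruteforce(self):
        rng = np.random.default_rng(3)
        img = rng.random((8, 8))
        feats = glcm_features(img, levels=8)
        expected = brute_force_glcm_props(img, 8, (0, 1))  # angle 0 deg
        assert np.allclose(feats[0:4], expected, atol=1e-10)

    def test_checkerboard_contrast(self):
        cb = (np.indices((4, 4)).sum(axis=0) % 2).astype(float)
        # every horizontal neighbor pair differs by one quantized level
        assert glcm_features(cb, levels=2)[0] == pytest.approx(1.0)

    def test_rotation_swaps_0_and_90_degree_blocks(self):
        rng = np.random.default_rng(7)
        img = np.sort(rng.random((10, 10)), axis=1)  # anisotropic
        orig = glcm_features(img, levels=8)
        rot = glcm_features(np.rot90(img), levels=8)
        assert np.allclose(orig[0:5], rot[10:15], atol=1e-12)
        assert np.allclose(orig[10:15], rot[0:5], atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            glcm_features(np.ones((1, 5)))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_property_ranges(self, seed):
        img = np.random.default_rng(seed).random((9, 9))
        f = glcm_features(img)
        for a in range(3):
            contrast, dissim, homog, energy, _ = f[5 * a:5 * a + 5]
            assert contrast >= 0 and dissim >= 0
            assert 0 < homog <= 1 and 0 < energy <= 1


class TestLBP:
    def test_histogram_is_probability_vector(self):
        h = lbp_features(np.random.default_rng(0).random((16, 16)))
        assert len(h) == 25
        assert h.min() >= 0
        assert h.sum() == pytest.approx(1.0)

    def test_constant_image_single_bin(self):
        h = lbp_features(np.full((8, 8), 0.3))
        # ties count as 1 -> code 255 -> last bin
        assert h[24] == 1.0 and h[:24].sum() == 0.0

    def test_hand_computed_code(self):
        # center 0.5; E,N,W,S neighbors are 1 (bits 0,2,4,6), diagonals 0
        img = np.array([[0.0, 1.0, 0.0],
                        [1.0, 0.5, 1.0],
                        [0.0, 1.0, 0.0]])
        assert lbp_codes(img)[0, 0] == 1 + 4 + 16 + 64

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            lbp_features(np.ones((2, 4)))


class TestShape:
    def test_filled_square_area(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 1.0
        area, perimeter, compactness = shape_features(img)
        assert area == 100
        assert perimeter > 0 and compactness > 0

    def test_disk_more_compact_than_bar(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2).astype(float)
        bar = np.zeros((4, 420))
        bar[1, 10:410] = 1.0
        assert shape_features(disk)[2] > shape_features(bar)[2]

    def test_all_zero_image_degenerate(self):
        assert np.array_equal(shape_features(np.zeros((8, 8))), np.zeros(3))


class TestIntensity:
    def test_constant(self):
        assert np.allclose(intensity_features(np.full((4, 4), 0.3)),
                           [0.3, 0, 0.3, 0, 0])

    def test_symmetric_two_point(self):
        f = intensity_features(np.array([0.0, 0.0, 1.0, 1.0]))
        assert f[0] == 0.5 and f[2] == 0.5 and f[3] == pytest.approx(0.0)

    def test_skewness_matches_moment_formula(self):
        x = np.array([0.0, 0.0, 0.0, 1.0])
        mean = x.mean()
        m2 = ((x - mean) ** 2).mean()
        m3 = ((x - mean) ** 3).mean()
        assert intensity_features(x)[3] == pytest.approx(m3 / m2 ** 1.5)


class TestScaler:
    def test_two_point_standardization(self):
        rows = np.array([[0.0], [2.0]])
        z = FeatureScaler().fit_transform(rows)
        assert np.allclose(z.ravel(), [-1.0, 1.0])

    def test_train_statistics_reused_on_heldout(self):
        train = np.array([[0.0], [2.0]])
        scaler = FeatureScaler().fit(train)
        assert scaler.transform(np.array([[4.0]]))[0, 0] == pytest.approx(3.0)

    def test_zero_variance_passthrough_with_warning(self, caplog):
        rows = np.array([[1.0, 0.0], [1.0, 2.0]])
        with caplog.at_level("WARNING"):
            scaler = FeatureScaler().fit(rows)
        assert scaler.sd_[0] == 1.0
        assert "zero-variance" in caplog.text

    def test_fit_on_self_gives_unit_moments(self):
        rows = np.random.default_rng(0).random((50, 7))
        z = FeatureScaler().fit_transform(rows)
        assert np.abs(z.mean(axis=0)).max() < 1e-8
        assert np.abs(z.var(axis=0) - 1).max() < 1e-6

    def test_empty_fit_rejected(self):
        with pytest.raises(ValueError):
            FeatureScaler().fit(np.empty((0, 3)))


class TestAttentionGate:
    def test_zero_parameters_halve(self):
        deep = np.arange(4.0)
        assert np.allclose(attention_gate_deep(deep, np.zeros(4)), 0.5 * deep)

    def test_sigmoid_ln3_hand_value(self):
        assert attention_gate_deep(np.array([2.0]),
                                   np.array([np.log(3.0)]))[0] == pytest.approx(1.5)

    def test_saturation_bound(self):
        deep = np.array([-3.0, 5.0])
        out = attention_gate_deep(deep, np.array([50.0, 50.0]))
        assert np.all(np.abs(out) <= np.abs(deep) + 1e-12)
        assert np.allclose(out, deep, atol=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attention_gate_deep(np.zeros(4), np.zeros(3))

    def test_fitted_gate_is_finite_and_reusable(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 8))
        y = (X[:, 0] > 0).astype(int)
        w = fit_attention_gate(X, y, seed=0)
        assert w.shape == (8,) and np.all(np.isfinite(w))


class TestFusion:
    def test_length_176(self):
        fused = fuse_features(np.zeros(40), np.zeros(3), np.zeros(5), np.zeros(128))
        assert fused.shape == (N_FUSED,)
        assert N_FUSED == 176

    def test_ordering_contract(self):
        texture = np.arange(40.0)
        fused = fuse_features(texture, np.zeros(3), np.zeros(5), np.zeros(128))
        assert np.array_equal(fused[:40], texture)

    def test_wrong_block_named_in_error(self):
        with pytest.raises(ValueError, match="shape"):
            fuse_features(np.zeros(40), np.zeros(4), np.zeros(5), np.zeros(128))


class TestDeepFeatures:
    def test_length_128_and_deterministic(self, tiny_trained_model, small_arrays):
        X = small_arrays[0][:3]
        f1 = extract_deep_features(tiny_trained_model, X)
        f2 = extract_deep_features(tiny_trained_model, X)
        assert f1.shape == (3, 128)
        assert np.array_equal(f1, f2)

    def test_zero_weights_give_zero_vector(self):
        model = models.build_simple_cnn(models.ModelSpec("simple_cnn", input_size=32))
        for p in model.params():
            p[...] = 0.0
        feats = extract_deep_features(model, np.random.default_rng(0).random((2, 32, 32)))
        assert np.allclose(feats, 0.0)


class TestFusedPipeline:
    def test_cancer_vs_noncancer_fused_means_differ(self, tiny_trained_model,
                                                    small_arrays):
        X, y, _ = small_arrays
        pipe = FusedFeaturePipeline(tiny_trained_model, seed=0)
        fused = pipe.fit_transform(X, y)
        assert fused.shape == (len(X), 176)
        gap = np.abs(fused[y == 1].mean(axis=0) - fused[y == 0].mean(axis=0))
        pooled_sd = fused.std(axis=0)
        effect = gap / np.where(pooled_sd == 0, 1.0, pooled_sd)
        assert effect.max() > 0.5  # at least one clearly separating dimension

    def test_transform_before_fit_rejected(self, tiny_trained_model, small_arrays):
        with pytest.raises(ValueError):
            FusedFeaturePipeline(tiny_trained_model).transform(small_arrays[0][:1])

    def test_handcrafted_block_width(self, small_arrays):
        assert handcrafted_features(small_arrays[0][0]).shape == (48,)
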