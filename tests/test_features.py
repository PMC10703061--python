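"""GLCM counting/statistics, conv filter bank, fusion."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from oracles import conv_bank_oracle
from rbscreen.core import FeatureVector
from rbscreen.features import (ConvBankConfig, GLCMConfig, compute_glcm,
                               conv_filterbank_features, fuse_features,
                               glcm_statistics, handcrafted_features,
                               quantize_gray)


class TestQuantize:
    @pytest.mark.parametrize("value, expected", [(0, 0), (127, 0), (128, 1), (255, 1)])
    def test_two_level_binning(self, value, expected):
        img = np.full((3, 3), value, dtype=np.uint8)
        assert (quantize_gray(img, 2) == expected).all()

    def test_histogram_matches_per_pixel_binning(self, rng):
        img = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        L = 8
        got = np.bincount(quantize_gray(img, L).ravel(), minlength=L)
        expected = np.zeros(L, dtype=int)
        for v in img.ravel():
            expected[min(int(v) * L // 256, L - 1)] += 1
        assert np.array_equal(got, expected)


class TestComputeGLCM:
    def test_worked_horizontal_example(self):
        img = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 2]])
        cfg = GLCMConfig(levels=3, symmetric=False, normalize=False)
        C = compute_glcm(img, (0, 1), cfg).matrix
        assert np.array_equal(C, [[1, 2, 0], [0, 2, 1], [0, 0, 0]])

    def test_constant_image_single_entry(self):
        n, v = 6, 2
        img = np.full((n, n), v)
        cfg = GLCMConfig(levels=4, symmetric=False, normalize=False)
        C = compute_glcm(img, (0, 1), cfg).matrix
        assert C[v, v] == n * (n - 1)
        assert C.sum() == n * (n - 1)

    def test_symmetric_equals_count_plus_transpose(self, rng):
        for _ in range(20):
            img = rng.integers(0, 4, size=(8, 8))
            asym = GLCMConfig(levels=4, symmetric=False, normalize=False)
            sym = GLCMConfig(levels=4, symmetric=True, normalize=False)
            A = compute_glcm(img, (1, 1), asym).matrix
            S = compute_glcm(img, (1, 1), sym).matrix
            assert np.array_equal(S, A + A.T)

    def test_matches_skimage_reference(self, rng):
        img = rng.integers(0, 4, size=(12, 12)).astype(np.uint8)
        # skimage angle 0 pairs (r, c) with (r, c+1); pi/2 with (r+1, c)
        for offset, angle in (((0, 1), 0.0), ((1, 0), np.pi / 2)):
            ref = graycomatrix(img, [1], [angle], levels=4,
                               symmetric=False, normed=False)[:, :, 0, 0]
            cfg = GLCMConfig(levels=4, symmetric=False, normalize=False)
            assert np.array_equal(compute_glcm(img, offset, cfg).matrix, ref)

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError):
            compute_glcm(np.array([[0, 9]]), (0, 1), GLCMConfig(levels=4))

    def test_normalized_sums_to_one(self, rng):
        img = rng.integers(0, 8, size=(9, 9))
        C = compute_glcm(img, (1, -1), GLCMConfig(levels=8)).matrix
        assert abs(C.sum() - 1.0) < 1e-9


class TestGLCMStatistics:
    def test_single_mass_limits(self):
        p = np.zeros((2, 2))
        p[1, 1] = 1.0
        from rbscreen.features import GLCMatrix
        stats = glcm_statistics(GLCMatrix(p, (0, 1), True))
        assert stats.contrast == 0.0
        assert stats.energy == 1.0
        assert stats.homogeneity == 1.0
        assert stats.correlation == 0.0 and stats.degenerate_correlation

    def test_diagonal_mass(self):
        from rbscreen.features import GLCMatrix
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        stats = glcm_statistics(GLCMatrix(p, (0, 1), True))
        assert abs(stats.contrast - 0.0) < 1e-12
        assert abs(stats.energy - 0.5) < 1e-12
        assert abs(stats.homogeneity - 1.0) < 1e-12
        assert abs(stats.correlation - 1.0) < 1e-12

    def test_antidiagonal_mass(self):
        from rbscreen.features import GLCMatrix
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        stats = glcm_statistics(GLCMatrix(p, (0, 1), True))
        assert abs(stats.contrast - 1.0) < 1e-12
        assert abs(stats.energy - 0.5) < 1e-12
        assert abs(stats.homogeneity - 0.5) < 1e-12
        assert abs(stats.correlation + 1.0) < 1e-12

    def test_unnormalized_rejected(self):
        from rbscreen.features import GLCMatrix
        with pytest.raises(ValueError):
            glcm_statistics(GLCMatrix(np.ones((2, 2)), (0, 1), False))

    def test_statistics_within_analytic_ranges(self, rng):
        from rbscreen.features import GLCMatrix
        for _ in range(20):
            img = rng.integers(0, 6, size=(10, 10))
            C = compute_glcm(img, (0, 1), GLCMConfig(levels=6))
            s = glcm_statistics(C)
            assert s.contrast >= 0
            assert 0 < s.energy <= 1
            assert 0 < s.homogeneity <= 1
            assert -1 - 1e-12 <= s.correlation <= 1 + 1e-12


class TestHandcrafted:
    def test_default_vector_length(self, rng):
        img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        vec = handcrafted_features(img)
        assert len(vec) == 16
        assert vec.names[0].startswith("glcm[0,1]")

    def test_transpose_offset_symmetry(self, rng):
        img = rng.integers(0, 256, size=(12, 14)).astype(np.uint8)
        a = handcrafted_features(img, GLCMConfig(offsets=((0, 1),)))
        b = handcrafted_features(img.T, GLCMConfig(offsets=((1, 0),)))
        assert np.allclose(a.values, b.values)


class TestConvFilterBank:
    def test_outputs_nonnegative(self, rng):
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        vec = conv_filterbank_features(img, ConvBankConfig(n_filters=4, seed=1))
        assert (vec.values >= 0).all()

    def test_zero_image_zero_bias_gives_zeros(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        vec = conv_filterbank_features(img, ConvBankConfig(n_filters=3, seed=0))
        assert np.allclose(vec.values, 0.0)

    def test_matches_nested_loop_oracle(self, rng):
        cfg = ConvBankConfig(n_filters=1, kernel=3, stride=1, pool=2, seed=9)
        for _ in range(5):
            img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
            vec = conv_filterbank_features(img, cfg)
            from rbscreen.features import filter_bank_kernels
            expected = conv_bank_oracle(img.astype(float) / 255.0,
                                        filter_bank_kernels(cfg)[0], 0.0, 1, 2)
            assert np.allclose(vec.values, expected.ravel())

    def test_brightening_monotone_with_nonnegative_kernels(self, rng):
        cfg = ConvBankConfig(n_filters=2, seed=3)
        from rbscreen.features import filter_bank_kernels
        kernels = np.abs(filter_bank_kernels(cfg))
        img = rng.integers(0, 200, size=(10, 10)).astype(np.uint8)
        base = conv_filterbank_features(img, cfg, kernels=kernels)
        brighter = conv_filterbank_features(np.clip(img + 30, 0, 255).astype(np.uint8),
                                            cfg, kernels=kernels)
        assert (brighter.values >= base.values - 1e-12).all()

    def test_pool_larger_than_map_rejected(self, rng):
        img = rng.integers(0, 256, size=(6, 6)).astype(np.uint8)
        with pytest.raises(ValueError):
            conv_filterbank_features(img, ConvBankConfig(pool=5))

    def test_deterministic_given_seed(self, rng):
        img = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        a = conv_filterbank_features(img, ConvBankConfig(seed=7))
        b = conv_filterbank_features(img, ConvBankConfig(seed=7))
        assert np.array_equal(a.values, b.values)


class TestFusion:
    def test_concatenation_order_and_length(self):
        a = FeatureVector([1.0, 2.0], ["a1", "a2"])
        b = FeatureVector([3.0], ["b1"])
        fused = fuse_features(a, b)
        assert len(fused) == 3
        assert np.array_equal(fused.values[:2], a.values)
        assert fused.names == ["a1", "a2", "b1"]

    def test_empty_identity(self):
        a = FeatureVector([1.0, 2.0], ["a1", "a2"])
        empty = FeatureVector([], [])
        assert fuse_features(a, empty).names == a.names
        assert fuse_features(empty, a).names == a.names

    def test_name_collision_rejected(self):
        a = FeatureVector([1.0], ["x"])
        b = FeatureVector([2.0], ["x"])
        with pytest.raises(ValueError):
            fuse_features(a, b)
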