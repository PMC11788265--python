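import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctdr.degrade import (
    FilterKernel,
    NoiseModel,
    add_noise,
    apply_lowpass,
    boxcar_gaussian_equivalent,
)
from ctdr.volumes import Volume


def uniform_vol(value=0.0, shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0)):
    return Volume(np.full(shape, float(value)), spacing)


FULL = np.ones((20, 20, 20), bool)


class TestKernelWeights:
    def test_boxcar_integer_voxels(self):
        w = FilterKernel("boxcar", 3.0).weights_1d(1.0)
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3])

    def test_boxcar_fractional_end_weights(self):
        # 4 mm boxcar on 1.5 mm voxels: symmetric kernel, end voxels overlap
        # [-2, 2] only partially (1.25 of their 1.5 mm footprint)
        w = FilterKernel("boxcar", 4.0).weights_1d(1.5)
        np.testing.assert_allclose(w, np.array([1.25, 1.5, 1.25]) / 4.0)

    def test_boxcar_even_ratio_zero_phase_noise_exact(self):
        # 2-voxel boxcar: odd symmetric kernel pooling exactly 2 voxels
        w = FilterKernel("boxcar", 4.0).weights_1d(2.0)
        np.testing.assert_allclose(w, [1 / 6, 2 / 3, 1 / 6])
        np.testing.assert_allclose((w**2).sum(), 0.5)
        w4 = FilterKernel("boxcar", 4.0).weights_1d(1.0)
        assert len(w4) == 5 and abs((w4**2).sum() - 0.25) < 1e-12

    def test_gaussian_truncation_and_normalization(self):
        k = FilterKernel("gaussian", 4.0, truncation=4.0)
        w = k.weights_1d(1.0)
        assert abs(w.sum() - 1.0) < 1e-12
        sigma_vox = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        assert len(w) == 2 * int(np.ceil(4 * sigma_vox)) + 1

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(width=st.floats(0.1, 20), spacing=st.floats(0.5, 3.0),
           kind=st.sampled_from(["boxcar", "gaussian"]))
    def test_weights_sum_to_one(self, width, spacing, kind):
        w = FilterKernel(kind, width).weights_1d(spacing)
        assert abs(w.sum() - 1.0) < 1e-9

    def test_boxcar_variance_matches_uniform_distribution(self):
        """Monte-Carlo: std of a uniform distribution of width w is w/sqrt(12)."""
        rng = np.random.default_rng(0)
        w = 4.0
        assert abs(rng.uniform(-w / 2, w / 2, 400_000).std() - w / np.sqrt(12)) < 0.01


class TestApplyLowpass:
    def test_uniform_unchanged(self):
        v = uniform_vol(0.0)
        out, _ = apply_lowpass(v, FilterKernel("boxcar", 5.0), FULL)
        np.testing.assert_allclose(out.data[3:-3, 3:-3, 3:-3], 0.0, atol=1e-9)

    def test_width_zero_identity(self):
        v = Volume(np.random.default_rng(0).normal(size=(10, 10, 10)), (1, 1, 1))
        out, ext = apply_lowpass(v, FilterKernel("boxcar", 0.0), FULL[:10, :10, :10])
        np.testing.assert_array_equal(out.data, v.data)

    def test_impulse_arithmetic(self):
        """3 mm boxcar on 1 mm voxels spreads an impulse into a 3^3 cube."""
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 999.0
        out, _ = apply_lowpass(
            Volume(data, (1, 1, 1)), FilterKernel("boxcar", 3.0), np.ones((9, 9, 9), bool)
        )
        assert abs(out.data[4, 4, 4] - 999.0 / 27.0) < 1e-9
        np.testing.assert_allclose(out.data[3:6, 3:6, 3:6], 999.0 / 27.0, atol=1e-9)
        assert abs(out.data[4, 4, 6]) < 1e-9

    def test_white_noise_variance_reduction(self):
        """A 4 mm boxcar on 1 mm voxels averages 64 voxels: noise std / 8."""
        rng = np.random.default_rng(1)
        v = Volume(rng.normal(0, 12.0, size=(100, 100, 100)), (1, 1, 1))
        out, _ = apply_lowpass(v, FilterKernel("boxcar", 4.0), np.ones(v.shape, bool))
        inner = out.data[5:-5, 5:-5, 5:-5]
        assert abs(inner.std() - 12.0 / 8.0) < 0.05 * (12.0 / 8.0)

    def test_mean_preserved_in_interior(self):
        rng = np.random.default_rng(2)
        v = Volume(rng.normal(40.0, 10.0, size=(40, 40, 40)), (1, 1, 1))
        for kind in ("boxcar", "gaussian"):
            out, _ = apply_lowpass(v, FilterKernel(kind, 6.0), np.ones(v.shape, bool))
            inner = (slice(13, -13),) * 3
            assert abs(out.data[inner].mean() - v.data[inner].mean()) < 0.1

    def test_variance_equivalence_boxcar_gaussian(self):
        """boxcar(w) and gaussian(sigma = w/sqrt(12)) leave white noise with
        the same std within 5% (the equal-second-moment Gaussian pools ~2%
        more noise per axis than the boxcar, an inherent shape difference)."""
        rng = np.random.default_rng(3)
        v = Volume(rng.normal(0, 10.0, size=(90, 90, 90)), (1, 1, 1))
        _, fwhm = boxcar_gaussian_equivalent(5.0)
        b, _ = apply_lowpass(v, FilterKernel("boxcar", 5.0), np.ones(v.shape, bool))
        g, _ = apply_lowpass(v, FilterKernel("gaussian", fwhm), np.ones(v.shape, bool))
        inner = (slice(8, -8),) * 3
        sb, sg = b.data[inner].std(), g.data[inner].std()
        assert abs(sb - sg) / sb < 0.05

    def test_kernel_wider_than_grid_rejected(self):
        v = uniform_vol(shape=(10, 10, 10))
        with pytest.raises(ValueError, match="exceeds"):
            apply_lowpass(v, FilterKernel("boxcar", 50.0), FULL[:10, :10, :10])

    def test_external_expanded_with_width(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[8:12, 8:12, 8:12] = True
        _, ext = apply_lowpass(uniform_vol(), FilterKernel("boxcar", 4.0), mask)
        assert ext.sum() > mask.sum()
        assert np.all(ext[mask])


class TestAddNoise:
    def test_sigma_zero_identity(self):
        v = uniform_vol(5.0)
        out = add_noise(v, NoiseModel(0.0, 1))
        np.testing.assert_array_equal(out.data, v.data)

    def test_seed_determinism(self):
        v = uniform_vol()
        a = add_noise(v, NoiseModel(10.0, 5))
        b = add_noise(v, NoiseModel(10.0, 5))
        np.testing.assert_array_equal(a.data, b.data)

    def test_sample_std_matches_sigma(self):
        v = Volume(np.zeros((60, 60, 60)), (1, 1, 1))
        out = add_noise(v, NoiseModel(12.0, 0))
        assert abs(out.data.std() - 12.0) < 0.01 * 12.0

    def test_noise_confined_to_external(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[:5] = True
        out = add_noise(uniform_vol(shape=(10, 10, 10)), NoiseModel(10.0, 2), mask)
        assert np.all(out.data[~mask] == 0.0)
        assert np.any(out.data[mask] != 0.0)

    def test_ordering_contract(self):
        """Noise added after filtering keeps its full sigma (the study's
        stated operation order)."""
        rng = np.random.default_rng(4)
        v = Volume(rng.normal(0, 5, size=(50, 50, 50)), (1, 1, 1))
        filt, ext = apply_lowpass(v, FilterKernel("boxcar", 4.0), np.ones(v.shape, bool))
        noisy = add_noise(filt, NoiseModel(20.0, 9), ext)
        added = noisy.data - filt.data
        assert abs(added.std() - 20.0) < 0.3


class TestBoxcarGaussianEquivalent:
    def test_four_mm_maps_to_2p7_fwhm(self):
        _, fwhm = boxcar_gaussian_equivalent(4.0)
        assert round(fwhm, 1) == 2.7

    def test_zero_width(self):
        assert boxcar_gaussian_equivalent(0.0) == (0.0, 0.0)

    def test_sigma_is_width_over_sqrt12(self):
        sigma, fwhm = boxcar_gaussian_equivalent(6.0)
        assert abs(sigma - 6.0 / np.sqrt(12)) < 1e-12
        assert abs(fwhm - 2 * np.sqrt(2 * np.log(2)) * sigma) < 1e-12
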