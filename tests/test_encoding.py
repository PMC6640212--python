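"""Visual front-end: filter kernels, filtering, normalization, latency coding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikewave.core import NO_SPIKE, validate_wave, wave_to_spike_times
from spikewave.encoding import (
    FilterBank,
    apply_filter_bank,
    generate_inhibition_kernel,
    intensity_lateral_inhibition,
    intensity_to_latency,
    local_normalization,
    make_dog_kernel,
    make_gabor_kernel,
)


def dog_oracle(window, s1, s2):
    """Direct evaluation of the two-Gaussian difference on the grid."""
    half = window // 2
    out = np.empty((window, window))
    for i in range(window):
        for j in range(window):
            r2 = (i - half) ** 2 + (j - half) ** 2
            g1 = np.exp(-r2 / (2 * s1**2)) / (2 * np.pi * s1**2)
            g2 = np.exp(-r2 / (2 * s2**2)) / (2 * np.pi * s2**2)
            out[i, j] = g1 - g2
    return out - out.mean()


class TestKernels:
    def test_dog_matches_direct_evaluation(self):
        got = make_dog_kernel(7, 1.0, 2.0)
        np.testing.assert_allclose(got, dog_oracle(7, 1.0, 2.0), atol=1e-12)

    def test_dog_swapped_widths_negate(self):
        np.testing.assert_allclose(
            make_dog_kernel(7, 1.0, 2.0), -make_dog_kernel(7, 2.0, 1.0), atol=1e-12
        )

    @pytest.mark.parametrize("maker,args", [
        (make_dog_kernel, (7, 1.0, 2.0)),
        (make_gabor_kernel, (9, 4.0, 0.7, 2.0, 0.8)),
    ])
    def test_kernels_sum_to_zero(self, maker, args):
        assert abs(maker(*args).sum()) < 1e-10

    def test_dog_equal_widths_rejected(self):
        with pytest.raises(ValueError):
            make_dog_kernel(7, 1.5, 1.5)

    @pytest.mark.parametrize("window", [4, 0, -3])
    def test_even_or_bad_window_rejected(self, window):
        with pytest.raises(ValueError):
            make_dog_kernel(window, 1.0, 2.0)

    def test_gabor_even_symmetry_theta_plus_pi(self):
        a = make_gabor_kernel(9, 3.0, 0.4, 2.0)
        b = make_gabor_kernel(9, 3.0, 0.4 + np.pi, 2.0)
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_gabor_rotation_reduces_to_axis_aligned(self):
        # evaluating the 0-orientation Gabor on a grid rotated by theta
        # must reproduce the theta-oriented kernel
        theta, window, lam, sigma, gamma = 0.6, 9, 4.0, 2.0, 0.9
        got = make_gabor_kernel(window, lam, theta, sigma, gamma)
        half = window // 2
        y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
        xr = x * np.cos(theta) + y * np.sin(theta)
        yr = -x * np.sin(theta) + y * np.cos(theta)
        oracle = np.exp(-(xr**2 + (gamma * yr) ** 2) / (2 * sigma**2)) * np.cos(
            2 * np.pi * xr / lam
        )
        oracle -= oracle.mean()
        np.testing.assert_allclose(got, oracle, atol=1e-10)


def filter_oracle(image, kernels, padding, clip):
    """Brute-force sliding-window cross-correlation."""
    padded = np.pad(image, padding)
    kh, kw = kernels[0].shape
    h = padded.shape[0] - kh + 1
    w = padded.shape[1] - kw + 1
    out = np.zeros((len(kernels), h, w))
    for f, k in enumerate(kernels):
        for i in range(h):
            for j in range(w):
                out[f, i, j] = (padded[i : i + kh, j : j + kw] * k).sum()
    out[out < clip] = 0.0
    return out


class TestFilterBank:
    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(20):
            image = rng.random((rng.integers(8, 17), rng.integers(8, 17)))
            kernels = [rng.standard_normal((5, 5)) for _ in range(3)]
            clip = float(rng.normal(0, 0.5))
            bank = FilterBank(kernels=kernels, padding=2, clip_threshold=clip)
            np.testing.assert_allclose(
                apply_filter_bank(image, bank),
                filter_oracle(image, kernels, 2, clip),
                atol=1e-10,
            )

    def test_zero_image_gives_zero_map(self):
        bank = FilterBank(kernels=[make_dog_kernel(5, 1, 2)], padding=2)
        assert not apply_filter_bank(np.zeros((10, 10)), bank).any()

    def test_clip_above_max_response_silences_everything(self, rng):
        image = rng.random((10, 10))
        bank = FilterBank(kernels=[np.ones((3, 3))], padding=1, clip_threshold=1e6)
        assert not apply_filter_bank(image, bank).any()

    def test_single_bright_pixel_stamps_kernel(self, rng):
        kernel = rng.standard_normal((3, 3))
        image = np.zeros((9, 9))
        image[4, 4] = 1.0
        bank = FilterBank(kernels=[kernel], padding=1, clip_threshold=-np.inf)
        out = apply_filter_bank(image, bank)
        # cross-correlation stamps the flipped kernel around the pixel
        np.testing.assert_allclose(out[0, 3:6, 3:6], kernel[::-1, ::-1], atol=1e-12)

    def test_mismatched_kernel_sizes_rejected(self):
        with pytest.raises(ValueError):
            FilterBank(kernels=[np.ones((3, 3)), np.ones((5, 5))])

    def test_padding_preserves_spatial_size(self, rng):
        bank = FilterBank(kernels=[make_dog_kernel(7, 1, 2)], padding=3)
        assert apply_filter_bank(rng.random((12, 15)), bank).shape == (1, 12, 15)


class TestLocalNormalization:
    def test_constant_map_normalizes_to_one(self):
        out = local_normalization(np.full((2, 8, 8), 3.7), region_size=3)
        np.testing.assert_allclose(out, 1.0, atol=1e-9)

    def test_scale_invariance(self, rng):
        m = rng.random((1, 10, 10)) + 0.1
        a = local_normalization(m, 5)
        b = local_normalization(100.0 * m, 5)
        np.testing.assert_allclose(a, b, rtol=1e-6)

    def test_matches_neighborhood_mean_oracle(self, rng):
        m = rng.random((2, 7, 7))
        region, eps = 3, 1e-12
        out = local_normalization(m, region, eps)
        padded = np.pad(m, ((0, 0), (1, 1), (1, 1)), mode="edge")
        for f in range(2):
            for i in range(7):
                for j in range(7):
                    mean = padded[f, i : i + region, j : j + region].mean()
                    assert out[f, i, j] == pytest.approx(m[f, i, j] / (mean + eps))

    def test_even_region_rejected(self):
        with pytest.raises(ValueError):
            local_normalization(np.ones((1, 4, 4)), 4)


class TestInhibitionKernel:
    def test_single_factor_gives_3x3_ring(self):
        np.testing.assert_array_equal(
            generate_inhibition_kernel([0.0]),
            [[0, 0, 0], [0, 1, 0], [0, 0, 0]],
        )

    def test_two_factors_give_chebyshev_rings(self):
        k = generate_inhibition_kernel([0.5, 0.9])
        assert k.shape == (5, 5)
        assert k[2, 2] == 1.0
        assert (k[1:4, 1:4][np.array([[1,1,1],[1,0,1],[1,1,1]], bool)] == 0.5).all()
        assert (k[0] == 0.9).all() and (k[-1] == 0.9).all()
        assert (k[:, 0] == 0.9).all() and (k[:, -1] == 0.9).all()

    def test_empty_factor_list_rejected(self):
        with pytest.raises(ValueError):
            generate_inhibition_kernel([])

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            generate_inhibition_kernel([1.5])


class TestIntensityLateralInhibition:
    def test_identity_kernel_leaves_map_unchanged(self, rng):
        m = rng.random((2, 6, 6))
        np.testing.assert_array_equal(
            intensity_lateral_inhibition(m, np.ones((3, 3))), m
        )

    def test_single_nonzero_pixel_unchanged(self):
        m = np.zeros((1, 5, 5))
        m[0, 2, 2] = 1.0
        out = intensity_lateral_inhibition(m, generate_inhibition_kernel([0.1]))
        np.testing.assert_array_equal(out, m)

    def test_two_adjacent_pixels_larger_suppresses_smaller(self):
        m = np.zeros((1, 3, 3))
        m[0, 1, 1] = 1.0
        m[0, 1, 2] = 0.6
        out = intensity_lateral_inhibition(m, generate_inhibition_kernel([0.5]))
        assert out[0, 1, 1] == 1.0  # winner untouched
        assert out[0, 1, 2] == pytest.approx(0.3)  # suppressed once, then mute

    def test_never_increases_intensity(self, rng):
        m = rng.random((3, 8, 8))
        out = intensity_lateral_inhibition(m, generate_inhibition_kernel([0.2, 0.7]))
        assert (out <= m + 1e-12).all()

    def test_factor_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            intensity_lateral_inhibition(np.ones((1, 3, 3)), np.full((3, 3), 2.0))


class TestIntensityToLatency:
    def test_strictly_decreasing_values_spike_in_rank_order(self):
        m = np.arange(9, 0, -1, dtype=float).reshape(1, 3, 3)
        grid = wave_to_spike_times(intensity_to_latency(m, t_max=9))
        np.testing.assert_array_equal(grid.times[0], np.arange(9).reshape(3, 3))

    def test_zero_map_never_spikes(self):
        assert not intensity_to_latency(np.zeros((2, 4, 4)), 5).any()

    def test_zero_intensities_stay_silent_among_spikes(self):
        m = np.array([[[3.0, 0.0], [1.0, 2.0]]])
        grid = wave_to_spike_times(intensity_to_latency(m, t_max=3))
        assert grid.times[0, 0, 1] == NO_SPIKE

    @given(seed=st.integers(0, 100), t_max=st.integers(1, 8))
    def test_monotone_latency_and_valid_wave(self, seed, t_max):
        rng = np.random.default_rng(seed)
        m = np.round(rng.random((2, 5, 5)), 2)  # rounding forces ties
        wave = intensity_to_latency(m, t_max)
        assert validate_wave(wave)
        times = wave_to_spike_times(wave).times.astype(float)
        times[times == NO_SPIKE] = np.inf
        flat_m, flat_t = m.reshape(-1), times.reshape(-1)
        for a in range(flat_m.size):
            for b in range(flat_m.size):
                if flat_m[a] > flat_m[b] > 0:
                    assert flat_t[a] <= flat_t[b]

    def test_bin_sizes_differ_by_at_most_one(self, rng):
        m = rng.random((1, 5, 5)) + 0.01  # 25 nonzero values
        wave = intensity_to_latency(m, t_max=4)
        per_step = np.diff(wave.sum(axis=(1, 2, 3)), prepend=0)
        assert per_step.max() - per_step.min() <= 1
        assert per_step.sum() == 25

    def test_row_major_tie_break(self):
        m = np.full((1, 2, 2), 0.5)
        grid = wave_to_spike_times(intensity_to_latency(m, t_max=4))
        np.testing.assert_array_equal(grid.times[0], [[0, 1], [2, 3]])

    def test_bad_t_max_rejected(self):
        with pytest.raises(ValueError):
            intensity_to_latency(np.ones((1, 2, 2)), 0)
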