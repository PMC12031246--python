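"""Extended-Sobel kernels: construction, application, class policy."""

import numpy as np
import pytest

from dolphinet import (
    DEFAULT_POLICY,
    VocalizationClass,
    apply_kernel,
    filter_for_class,
    make_kernel,
)
from dolphinet.edge_filter import VALID_SIZES
from dolphinet.spectrogram import SpectrogramImage


def brute_force_correlate(image, weights):
    """Dense nested-loop cross-correlation with reflect padding."""
    k = weights.shape[0]
    r = k // 2
    padded = np.pad(image, r, mode="symmetric")  # ndimage's "reflect"
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.sum(padded[i : i + k, j : j + k] * weights)
    return out


class TestKernelConstruction:
    def test_size3_time_is_canonical_sobel(self):
        kernel = make_kernel(3, "time")
        assert np.array_equal(
            kernel.weights, np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=float)
        )

    def test_size5_derivative_vector(self):
        kernel = make_kernel(5, "time")
        # every row is the smoothed central difference scaled by Pascal weights
        assert np.array_equal(kernel.weights[0], [1, 2, 0, -2, -1])
        assert np.array_equal(kernel.weights, np.outer([1, 4, 6, 4, 1], [1, 2, 0, -2, -1]))

    @pytest.mark.parametrize("size", VALID_SIZES)
    @pytest.mark.parametrize("axis", ["time", "frequency"])
    def test_invariants_all_sizes(self, size, axis):
        kernel = make_kernel(size, axis)
        w = kernel.weights
        assert w.shape == (size, size)
        assert w.sum() == 0.0
        flip = np.fliplr(w) if axis == "time" else np.flipud(w)
        assert np.array_equal(flip, -w)  # antisymmetric along derivative axis
        other = np.flipud(w) if axis == "time" else np.fliplr(w)
        assert np.array_equal(other, w)  # symmetric along smoothing axis
        transposed = kernel.transpose()
        assert transposed.derivative_axis != axis
        assert np.array_equal(transposed.weights, w.T)

    @pytest.mark.parametrize("size", [2, 4, 13, -1])
    def test_invalid_sizes_rejected(self, size):
        with pytest.raises(ValueError, match="size"):
            make_kernel(size, "time")


class TestApplyKernel:
    def test_matches_brute_force_on_random_images(self, rng):
        for _ in range(100):
            size = int(rng.choice(VALID_SIZES))
            axis = "time" if rng.random() < 0.5 else "frequency"
            kernel = make_kernel(size, axis)
            image = rng.random((20, 20))
            expected = np.abs(brute_force_correlate(image, kernel.weights))
            peak = expected.max()
            expected = np.full_like(expected, 0.5) if peak < 1e-12 else expected / peak
            got = apply_kernel(image, kernel)
            assert np.max(np.abs(got - expected)) < 1e-9

    def test_constant_image_degenerates_to_half(self):
        out = apply_kernel(np.full((30, 40), 0.7), make_kernel(7, "time"))
        assert np.all(out == 0.5)

    @pytest.mark.parametrize("size", VALID_SIZES)
    def test_annihilation_of_constant_along_derivative_axis(self, size, rng):
        rows = rng.random(30)
        horizontal_bands = np.tile(rows[:, None], (1, 50))  # constant along time
        response = np.abs(
            brute_force_correlate(horizontal_bands, make_kernel(size, "time").weights)
        )
        assert response.max() < 1e-9
        vertical_streaks = horizontal_bands.T  # constant along frequency
        response = np.abs(
            brute_force_correlate(vertical_streaks, make_kernel(size, "frequency").weights)
        )
        assert response.max() < 1e-9

    def test_single_column_response_at_flanks(self):
        image = np.zeros((30, 60))
        image[:, 30] = 1.0  # a synthetic click: one bright column
        out = apply_kernel(image, make_kernel(3, "time"))
        # response concentrated around the column, zero far away
        assert out[:, 29:32].max() == 1.0
        assert np.all(out[:, :27] == 0)
        assert np.all(out[:, 34:] == 0)
        # the same image is annihilated by the frequency-derivative kernel
        dual = np.abs(brute_force_correlate(image, make_kernel(3, "frequency").weights))
        assert dual.max() == 0

    def test_axis_duality_under_transpose(self, rng):
        image = rng.random((25, 35))
        k_time, k_freq = make_kernel(5, "time"), make_kernel(5, "frequency")
        a = apply_kernel(image.T, k_time).T
        b = apply_kernel(image, k_freq)
        # identical away from the reflect border
        assert np.allclose(a[3:-3, 3:-3], b[3:-3, 3:-3], atol=1e-12)


class TestFilterPolicy:
    def _image(self, klass):
        rng = np.random.default_rng(0)
        return SpectrogramImage(
            rng.random((150, 300)),
            np.linspace(0, 0.8, 300),
            np.linspace(3e3, 96e3, 150),
            VocalizationClass(klass),
        )

    def test_policy_directions(self):
        assert DEFAULT_POLICY.axis_for(VocalizationClass.WHISTLE) == "frequency"
        assert DEFAULT_POLICY.axis_for(VocalizationClass.NOISE) == "frequency"
        for klass in (2, 3, 4):
            assert DEFAULT_POLICY.axis_for(klass) == "time"

    def test_whistle_gets_frequency_kernel(self):
        image = self._image(VocalizationClass.WHISTLE)
        got = filter_for_class(image, size=3)
        expected = apply_kernel(image.pixels, make_kernel(3, "frequency"))
        assert np.array_equal(got.pixels, expected)

    def test_feeding_buzz_gets_time_kernel(self):
        image = self._image(VocalizationClass.FEEDING_BUZZ)
        got = filter_for_class(image, size=3)
        expected = apply_kernel(image.pixels, make_kernel(3, "time"))
        assert np.array_equal(got.pixels, expected)

    def test_default_size_is_seven(self):
        image = self._image(VocalizationClass.WHISTLE)
        got = filter_for_class(image)
        expected = apply_kernel(image.pixels, make_kernel(7, "frequency"))
        assert np.array_equal(got.pixels, expected)

    def test_deployment_without_direction_errors(self, rng):
        with pytest.raises(ValueError, match="direction"):
            filter_for_class(rng.random((150, 300)))

    def test_deployment_override(self, rng):
        pixels = rng.random((150, 300))
        got = filter_for_class(pixels, direction="time", size=5)
        expected = apply_kernel(pixels, make_kernel(5, "time"))
        assert np.array_equal(got, expected)
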