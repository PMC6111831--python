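"""Non-classical-receptive-field surround weights: kernels, local
statistics, similarity weights and the colour-orientation difference."""

import numpy as np
import pytest

import biocontour as bc
from biocontour.core import OrientationStack, orientation_grid
from biocontour.surround import (
    dog_plus_kernel,
    feature_modulation_weights,
    local_statistics,
    orientation_difference,
    raised_cosine_window,
)


class TestDogPlusKernel:
    def test_annulus_shape(self):
        wd = dog_plus_kernel(1.1, 4.0)
        c = wd.shape[0] // 2
        assert wd[c, c] == 0.0
        assert abs(wd.sum() - 1.0) < 1e-10
        assert wd.min() >= 0.0

    def test_radial_profile_rises_peaks_decays(self):
        wd = dog_plus_kernel(1.1, 4.0)
        c = wd.shape[0] // 2
        profile = wd[c, c:]
        peak = int(np.argmax(profile))
        assert peak > 0  # zero at the centre, positive ring away from it
        assert np.all(np.diff(profile[peak:]) <= 1e-15)

    def test_sub_unity_ratio_needs_strict_mode(self):
        with pytest.raises(ValueError):
            dog_plus_kernel(1.1, 0.4)
        blob = dog_plus_kernel(1.1, 0.4, strict=True)
        c = blob.shape[0] // 2
        # the printed ratio < 1 yields a centre blob, not a surround
        assert blob[c, c] == blob.max()


class TestRaisedCosineWindow:
    def test_centre_corners_and_symmetry(self):
        win = raised_cosine_window(11)
        assert win[5, 5] == 1.0
        assert win[0, 0] == 0.0 and win[0, -1] == 0.0
        assert np.allclose(win, np.rot90(win))

    def test_even_size_rejected(self):
        with pytest.raises(ValueError):
            raised_cosine_window(10)


class TestLocalStatistics:
    def test_uniform_image(self):
        img = np.full((24, 24, 3), 0.6)
        lum, contrast = local_statistics(img, raised_cosine_window(11))
        # constant raw statistics rescale to the zero field by convention
        assert np.all(lum == 0.0)
        assert np.all(contrast == 0.0)

    def test_checkerboard_beats_smooth_ramp_in_contrast(self):
        yy, xx = np.mgrid[0:32, 0:32]
        checker = ((yy + xx) % 2) * 0.5 + 0.25
        ramp = np.tile(np.linspace(0.25, 0.75, 32), (32, 1))
        win = raised_cosine_window(11)
        _, c_checker = local_statistics(np.stack([checker] * 3, -1), win,
                                        rescale=False)
        _, c_ramp = local_statistics(np.stack([ramp] * 3, -1), win,
                                     rescale=False)
        assert c_checker.mean() > c_ramp.mean()

    def test_luminance_preserves_half_plane_ordering(self):
        img = np.full((32, 32, 3), 0.25)
        img[:, 16:] = 0.75
        lum, _ = local_statistics(img, raised_cosine_window(11), rescale=False)
        assert lum[:, :8].mean() < lum[:, 24:].mean()


class TestFeatureModulationWeights:
    def test_uniform_statistic_gives_unit_weight(self):
        wd = dog_plus_kernel(1.1, 4.0)
        flat = np.full((40, 40), 0.3)
        w_l, w_c = feature_modulation_weights(flat, flat, wd, sigma1=0.05)
        assert np.allclose(w_l, 1.0, atol=1e-10)
        assert np.allclose(w_c, 1.0, atol=1e-10)

    def test_one_sigma_difference_scores_exp_minus_half(self):
        # single surround point of weight one at offset (0, +1)
        kernel = np.zeros((3, 3))
        kernel[1, 2] = 1.0
        sigma1 = 0.05
        lum = np.tile(np.arange(8) * sigma1, (8, 1))  # |ΔL| = σ1 between columns
        w_l, _ = feature_modulation_weights(lum, lum, kernel, sigma1)
        assert w_l[4, 3] == pytest.approx(np.exp(-0.5))

    def test_weights_lie_in_unit_interval(self):
        rng = np.random.default_rng(11)
        wd = dog_plus_kernel(1.1, 4.0)
        lum = rng.uniform(size=(32, 32))
        w_l, w_c = feature_modulation_weights(lum, lum**2, wd, sigma1=0.05)
        for field in (w_l, w_c):
            assert field.min() > 0.0
            assert field.max() <= 1.0 + 1e-12

    def test_matches_nested_loop_oracle(self):
        """Direct evaluation of the surround sum over the annulus support
        must coincide with the shifted-slab implementation."""
        rng = np.random.default_rng(12)
        img = rng.uniform(size=(16, 16, 3))
        win = raised_cosine_window(11)
        lum, contrast = local_statistics(img, win)
        wd = dog_plus_kernel(1.1, 4.0)
        w_l, w_c = feature_modulation_weights(lum, contrast, wd, sigma1=0.05)

        def oracle(feature):
            h, w = feature.shape
            radius = wd.shape[0] // 2
            padded = np.pad(feature, radius, mode="reflect")
            out = np.zeros_like(feature)
            for y in range(h):
                for x in range(w):
                    acc = 0.0
                    for ky in range(wd.shape[0]):
                        for kx in range(wd.shape[1]):
                            weight = wd[ky, kx]
                            if weight == 0.0:
                                continue
                            neighbour = padded[y + ky, x + kx]
                            diff = feature[y, x] - neighbour
                            acc += weight * np.exp(-diff * diff / (2 * 0.05**2))
                    out[y, x] = acc
            return out

        assert np.max(np.abs(oracle(lum) - w_l)) < 1e-6
        assert np.max(np.abs(oracle(contrast) - w_c)) < 1e-6


class TestOrientationDifference:
    def test_uniform_stack_maximises_suppression_weight(self):
        values = np.full((32, 32, 6), 0.4)
        stack = OrientationStack(values=values, orientations=orientation_grid(6))
        wd = dog_plus_kernel(1.1, 4.0)
        delta, w_theta = orientation_difference(stack, 1.1, wd, sigma2=0.2)
        assert np.allclose(delta, 0.0, atol=1e-10)
        assert np.allclose(w_theta, 1.0, atol=1e-10)

    def test_gaussian_attenuation_identity(self):
        rng = np.random.default_rng(13)
        values = rng.uniform(size=(24, 24, 6))
        stack = OrientationStack(values=values, orientations=orientation_grid(6))
        wd = dog_plus_kernel(1.1, 4.0)
        delta, w_theta = orientation_difference(stack, 1.1, wd, sigma2=0.2)
        assert np.allclose(w_theta, np.exp(-delta**2 / (2 * 0.2**2)), atol=1e-12)
        # exp(−Δθ²/2σ2²) at Δθ = σ2 is e^{−1/2}
        assert np.exp(-0.2**2 / (2 * 0.2**2)) == pytest.approx(np.exp(-0.5))

    def test_orientation_contrast_marks_the_texture_boundary(
        self, detect_textured_96, square_regions_96
    ):
        # the perimeter separates two bar orientations: its centre-surround
        # orientation difference exceeds the uniform-texture baseline
        *_, inter = detect_textured_96
        interior, perim = square_regions_96
        delta = inter["delta_theta"]
        assert delta[perim].mean() > delta[interior].mean()
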