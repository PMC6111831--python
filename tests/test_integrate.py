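"""Two-scale hierarchy orchestration, weight fusion and final inhibition."""

import numpy as np
import pytest

import biocontour as bc
from biocontour.integrate import combine_weights, final_contour
from biocontour.surround import dog_plus_kernel


class TestCombineWeights:
    @pytest.mark.parametrize(
        "delta,expected",
        [(+0.1, 0.9), (-0.1, 0.2), (0.0, 0.9)],  # ΔD = 0 takes the max branch
    )
    def test_branch_selection(self, delta, expected):
        shape = (4, 4)
        out = combine_weights(
            np.full(shape, 0.2), np.full(shape, 0.5), np.full(shape, 0.9),
            np.full(shape, delta),
        )
        assert np.allclose(out, expected)

    def test_mixed_sign_field(self):
        w1, w2, w3 = (np.full((2, 2), v) for v in (0.3, 0.6, 0.8))
        delta = np.array([[1.0, -1.0], [0.0, -0.5]])
        out = combine_weights(w1, w2, w3, delta)
        assert np.allclose(out, [[0.8, 0.3], [0.8, 0.3]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_weights(np.zeros((2, 2)), np.zeros((2, 2)),
                            np.zeros((2, 2)), np.zeros((3, 3)))


class TestFinalContour:
    def test_zero_attenuation_is_identity(self):
        rng = np.random.default_rng(14)
        d = rng.uniform(size=(24, 24))
        wd = dog_plus_kernel(1.1, 4.0)
        out = final_contour(d, np.ones_like(d), wd, alpha=0.0)
        assert np.array_equal(out, d)

    def test_zero_weight_is_identity(self):
        rng = np.random.default_rng(15)
        d = rng.uniform(size=(24, 24))
        wd = dog_plus_kernel(1.1, 4.0)
        assert np.array_equal(final_contour(d, np.zeros_like(d), wd, 1.0), d)

    def test_strong_inhibition_rectifies_to_zero(self):
        d = np.full((24, 24), 0.5)
        wd = dog_plus_kernel(1.1, 4.0)
        out = final_contour(d, np.ones_like(d), wd, alpha=10.0)
        assert np.all(out == 0.0)

    def test_monotone_nonincreasing_in_alpha(self):
        rng = np.random.default_rng(16)
        d = rng.uniform(size=(24, 24))
        w = rng.uniform(size=(24, 24))
        wd = dog_plus_kernel(1.1, 4.0)
        previous = None
        for alpha in (0.0, 0.5, 1.0, 2.0):
            out = final_contour(d, w, wd, alpha)
            if previous is not None:
                assert np.all(out <= previous + 1e-12)
            previous = out

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError):
            final_contour(np.zeros((8, 8)), np.zeros((8, 8)),
                          dog_plus_kernel(1.1, 4.0), alpha=-0.1)


class TestRunHierarchy:
    def test_constant_image_is_silent(self, params):
        img = np.full((32, 32, 3), 0.5)
        assert np.all(bc.run_hierarchy(img, params) == 0.0)

    def test_feedback_only_adds(self, params, isoluminant_64):
        from biocontour.lgn import single_opponent
        from biocontour.v1 import v1_response
        from biocontour.v2 import combine_feedforward_feedback, v2_pool

        img, _ = isoluminant_64
        v1 = v1_response(single_opponent(img, params), params.sigma, params)
        pooled = v2_pool(v1, params)
        with_fb = combine_feedforward_feedback(pooled, rescale=False)
        without = combine_feedforward_feedback(pooled, feedback=False,
                                               rescale=False)
        assert np.all(with_fb >= without)

    def test_output_normalised(self, params, isoluminant_64):
        img, _ = isoluminant_64
        d = bc.run_hierarchy(img, params)
        assert d.min() >= 0.0
        assert d.max() == pytest.approx(1.0)


class TestDetect:
    def test_deterministic_bit_identical(self, params):
        img, _ = bc.generate(bc.StimulusSpec(kind="cluttered_scene",
                                             size=(48, 48), seed=0))
        assert np.array_equal(bc.detect(img, params), bc.detect(img, params))

    def test_output_bounded_by_fine_response(self, detect_textured_96):
        _, _, cd, inter = detect_textured_96
        assert np.all(cd <= inter["fine"] + 1e-12)
        assert cd.min() >= 0.0

    def test_isoluminant_boundary_dominates(self, params, isoluminant_64):
        # purely chromatic boundary: the detector's response on the
        # ground-truth column towers over the background
        img, gt = isoluminant_64
        cd = bc.detect(img, params)
        col = gt.consensus.astype(bool)
        from scipy import ndimage
        band = ndimage.binary_dilation(col, iterations=1)
        assert cd[col].max() > 5.0 * cd[~band].mean()

    def test_surround_inhibition_improves_cluttered_scene(self, params,
                                                          cluttered_96):
        img, gt = cluttered_96
        cd = bc.detect(img, params)
        fine = bc.run_hierarchy(img, params)
        best_full = bc.pr_curve(cd, gt, n_thresholds=30, tol=3.5).best_f
        best_fine = bc.pr_curve(fine, gt, n_thresholds=30, tol=3.5).best_f
        assert best_full >= best_fine

    def test_texture_suppressed_more_than_contour(self, detect_textured_96,
                                                  square_regions_96):
        _, _, cd, inter = detect_textured_96
        interior, perim = square_regions_96
        d = inter["fine"]
        supp_interior = (d[interior].mean() - cd[interior].mean()) / d[interior].mean()
        supp_perim = (d[perim].mean() - cd[perim].mean()) / d[perim].mean()
        assert supp_interior > supp_perim

    def test_translation_covariance_on_interior(self, params):
        # shifting a luminance edge shifts the response map with it
        img, _ = bc.generate(bc.StimulusSpec(kind="two_tone_edge",
                                             size=(48, 96), seed=0))
        shifted = np.roll(img, 5, axis=1)
        a = bc.detect(img, params)
        b = bc.detect(shifted, params)
        inner = np.s_[4:-4, 40:56]
        assert np.allclose(np.roll(a, 5, axis=1)[inner], b[inner], atol=1e-6)
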