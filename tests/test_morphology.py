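"""Lumen morphology features: closed-form geometry checks and assembly."""

import numpy as np
import pytest

from octaline.data import LumenContour
from octaline.morphology import (
    MorphologyFeatureExtractor,
    aline_signed_distance,
    fit_lumen_lines,
    frame_eccentricity,
    lumen_area,
    lumen_slope,
)
from tests.conftest import circle_contour, ellipse_contour


class TestLumenArea:
    def test_circle_closed_form(self):
        contour = circle_contour(radius=200.0)  # 200 px = 1 mm at 5 µm pitch
        area = lumen_area(contour, radial_pitch_mm=0.005)
        assert area == pytest.approx(np.pi, rel=0.005)

    def test_scaling_homogeneity(self):
        c1 = circle_contour(150.0)
        c2 = circle_contour(300.0)
        assert lumen_area(c2) == pytest.approx(4 * lumen_area(c1), rel=1e-6)

    def test_ellipse_closed_form(self):
        contour = ellipse_contour(a=200.0, b=100.0)
        area = lumen_area(contour, radial_pitch_mm=0.005)
        assert area == pytest.approx(np.pi / 2, rel=0.005)

    def test_too_few_valid_points_rejected(self):
        contour = LumenContour(
            boundary_r=np.full(16, 10.0),
            valid_mask=np.array([True, True] + [False] * 14),
        )
        with pytest.raises(ValueError):
            lumen_area(contour)


class TestEccentricity:
    def test_circle_is_zero(self):
        assert frame_eccentricity(circle_contour(150.0)) == pytest.approx(0.0, abs=1e-3)

    def test_two_to_one_ellipse(self):
        e = frame_eccentricity(ellipse_contour(a=180.0, b=90.0))
        assert e == pytest.approx(np.sqrt(3) / 2, abs=0.01)

    @pytest.mark.parametrize("phase", [0.3, 1.1, 2.5])
    def test_rotation_invariance(self, phase):
        e0 = frame_eccentricity(ellipse_contour(a=180.0, b=120.0))
        e1 = frame_eccentricity(ellipse_contour(a=180.0, b=120.0, phase=phase))
        assert e1 == pytest.approx(e0, abs=1e-3)


class TestSignedDistance:
    def test_centered_circle_all_zero(self):
        d = aline_signed_distance(circle_contour(150.0))
        assert np.abs(d).max() <= 1.0

    def test_arc_length_weighted_sum_vanishes(self):
        """Equal-area constraint: ∮ d dℓ ≈ 0 for any contour (first order)."""
        contour = ellipse_contour(a=180.0, b=120.0, phase=0.4)
        d = aline_signed_distance(contour)
        from octaline.morphology import contour_xy

        xy = contour_xy(contour)
        seg = np.linalg.norm(np.roll(xy, -1, axis=0) - xy, axis=1)
        weighted = (d * seg).sum() / seg.sum()
        assert abs(weighted) <= 0.02 * 150.0  # within 2% of the mean radius

    def test_flattened_span_goes_negative(self):
        """A locally flattened wall lies inside the equal-area circle."""
        from octaline.phantom import Lesion, PhantomConfig, generate_pullback

        les = Lesion("calcium", theta_start=200, theta_extent=100, z_start=0, z_extent=1)
        cfg = PhantomConfig(
            n_frames=1, eccentricity_amplitude=0.0, lesions=[les],
            guidewire_width=0, speckle_shape=0.0, seed=0,
        )
        _, _, contours, _ = generate_pullback(cfg)
        d = aline_signed_distance(contours[0])
        mid = les.theta_indices(496)[40:60]
        assert d[mid].max() < 0


class TestFitLines:
    def test_collinear_window_perfect_fit(self):
        # square-ish contour: make one side exactly straight in Cartesian space
        n = 64
        t = 2 * np.pi * np.arange(n) / n
        r = 100.0 / np.maximum(np.abs(np.cos(t)), np.abs(np.sin(t)))
        out = fit_lumen_lines(LumenContour(boundary_r=r))
        # windows of n/8 = 8 points centered inside a flat side are collinear
        assert out["ssr"].min() == pytest.approx(0.0, abs=1e-8)
        assert out["r2"].max() == pytest.approx(1.0, abs=1e-8)

    def test_circle_symmetry_equal_ssr(self):
        out = fit_lumen_lines(circle_contour(150.0, n_theta=496))
        assert out["ssr"].std() / out["ssr"].mean() <= 0.05

    def test_flat_span_minimizes_ssr(self):
        from octaline.phantom import Lesion, PhantomConfig, generate_pullback

        les = Lesion("calcium", theta_start=100, theta_extent=124, z_start=0, z_extent=1)
        cfg = PhantomConfig(
            n_frames=1, eccentricity_amplitude=0.0, lesions=[les],
            guidewire_width=0, speckle_shape=0.0, seed=0,
        )
        _, _, contours, _ = generate_pullback(cfg)
        out = fit_lumen_lines(contours[0])
        span = les.theta_indices(496)
        assert np.argmin(out["ssr"]) in span

    def test_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            fit_lumen_lines(circle_contour(10.0, n_theta=16))


class TestLumenSlope:
    def test_concentric_circle_zero_slope(self):
        slope = lumen_slope(circle_contour(150.0))
        assert np.abs(slope).max() <= 0.1

    def test_offset_circle_sinusoidal_zero_mean(self):
        """r(θ) of an offset circle is ≈ R + d·cos(θ − φ): the slope profile
        is sinusoidal with zero mean."""
        n = 496
        t = 2 * np.pi * np.arange(n) / n
        d, R = 30.0, 150.0
        r = d * np.cos(t) + np.sqrt(R**2 - (d * np.sin(t)) ** 2)
        slope = lumen_slope(LumenContour(boundary_r=r))
        assert abs(slope.mean()) <= 1e-3
        expected_amp = d * 2 * np.pi / n  # derivative of d·cos(θ) in index units
        assert slope.max() == pytest.approx(expected_amp, rel=0.1)

    def test_reversed_contour_negates_slope(self):
        contour = ellipse_contour(a=180.0, b=120.0, phase=0.7)
        fwd = lumen_slope(contour)
        rev = lumen_slope(LumenContour(boundary_r=contour.boundary_r[::-1].copy()))
        np.testing.assert_allclose(rev, -fwd[::-1], atol=1e-9)


class TestAssembly:
    def test_constant_geometry_deltas_zero_ratios_one(self):
        contours = [circle_contour(150.0, n_theta=64) for _ in range(7)]
        ext = MorphologyFeatureExtractor()
        mat = ext.transform_pullback(contours)
        names = ext.feature_names
        assert mat.shape == (64 * 7, len(names))
        for j, name in enumerate(names):
            if "delta" in name:
                np.testing.assert_allclose(mat[:, j], 0.0, atol=1e-9)
            elif "ratio" in name:
                np.testing.assert_allclose(mat[:, j], 1.0, atol=1e-9)

    def test_edge_frames_clamp_and_flag(self):
        contours = [circle_contour(100.0 + 5 * z, n_theta=64) for z in range(8)]
        ext = MorphologyFeatureExtractor()
        mat = ext.transform_pullback(contours)
        names = ext.feature_names
        flag = names.index("edge_clamped")
        n_theta = 64
        assert mat[0, flag] == 1.0  # first frame clamps z−k
        assert mat[4 * n_theta, flag] == 0.0  # interior frame does not

    def test_rotationally_symmetric_input_uniform_over_theta(self):
        contours = [circle_contour(150.0, n_theta=64) for _ in range(3)]
        ext = MorphologyFeatureExtractor()
        mat = ext.transform_pullback(contours)
        frame0 = mat[:64]
        np.testing.assert_allclose(
            frame0, np.broadcast_to(frame0[0], frame0.shape), atol=1e-6
        )

    def test_pure_function_of_contours(self):
        contours = [ellipse_contour(180.0, 120.0, n_theta=64) for _ in range(3)]
        a = MorphologyFeatureExtractor().transform_pullback(contours)
        b = MorphologyFeatureExtractor().transform_pullback(contours)
        np.testing.assert_array_equal(a, b)
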