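"""Pre-processing: DP optimality oracles, segmentation recovery, pixel shift,
ROI crop and Gaussian denoising."""

import itertools

import numpy as np
import pytest
from dataclasses import replace

from octaline.data import LumenContour
from octaline.phantom import PhantomConfig, generate_pullback
from octaline.preprocess import (
    KEEP_LENGTH,
    ROI_LENGTH,
    crop_and_denoise,
    detect_guidewire,
    inverse_pixel_shift,
    optimal_closed_path,
    pixel_shift,
    segment_lumen,
    track_minimum_path,
)


def brute_force_closed_path(score: np.ndarray, max_jump: int) -> tuple[np.ndarray, float]:
    """Enumerate every jump-constrained closed path (tiny grids only)."""
    n_theta, n_r = score.shape
    offsets = np.asarray(
        list(itertools.product(range(-max_jump, max_jump + 1), repeat=n_theta - 1))
    )
    starts = np.arange(n_r)
    rows = starts[:, None, None] + np.concatenate(
        [np.zeros((offsets.shape[0], 1), dtype=int), np.cumsum(offsets, axis=1)], axis=1
    )[None, :, :]  # (n_start, n_paths, n_theta)
    valid = ((rows >= 0) & (rows < n_r)).all(axis=2)
    valid &= np.abs(rows[:, :, -1] - rows[:, :, 0]) <= max_jump
    # clip keeps indexing legal; invalid paths are masked to -inf anyway
    gathered = score[np.arange(n_theta)[None, None, :], rows.clip(0, n_r - 1)].sum(axis=2)
    totals = np.where(valid, gathered, -np.inf)
    best = np.unravel_index(np.argmax(totals), totals.shape)
    return rows[best], float(totals[best])


class TestClosedPathDP:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("n_theta,n_r,max_jump", [(8, 12, 2), (6, 12, 3), (8, 8, 1)])
    def test_matches_exhaustive_search(self, seed, n_theta, n_r, max_jump):
        rng = np.random.default_rng(seed)
        score = rng.normal(size=(n_theta, n_r))
        path = optimal_closed_path(score, max_jump=max_jump, start_candidates="all")
        _, best_total = brute_force_closed_path(score, max_jump)
        got = score[np.arange(n_theta), path].sum()
        assert got == pytest.approx(best_total)
        assert np.all(np.abs(np.diff(path)) <= max_jump)
        assert abs(path[0] - path[-1]) <= max_jump

    def test_circular_closure_constraint(self):
        rng = np.random.default_rng(3)
        score = rng.normal(size=(16, 30))
        path = optimal_closed_path(score, max_jump=3)
        assert abs(path[0] - path[-1]) <= 3


class TestGuidewireTracking:
    @pytest.mark.parametrize("seed", range(3))
    def test_dp_matches_exhaustive_on_tiny_maps(self, seed):
        rng = np.random.default_rng(seed)
        n_frames, n_states = 4, 8
        cost = rng.normal(size=(n_frames, n_states))
        lam = 0.3
        path = track_minimum_path(cost, lam)

        def total(states):
            t = sum(cost[z, s] for z, s in enumerate(states))
            for z in range(1, n_frames):
                d = abs(states[z] - states[z - 1])
                t += lam * min(d, n_states - d)
            return t

        best = min(
            itertools.product(range(n_states), repeat=n_frames), key=total
        )
        assert total(path.tolist()) == pytest.approx(total(best))

    def test_detects_static_shadow_center(self):
        cfg = PhantomConfig(
            n_frames=6, n_r=360, n_theta=496, lumen_radius_px=150.0,
            guidewire_center_theta=115, guidewire_width=30, wall_depth_px=200, seed=4,
        )
        pullback, *_ = generate_pullback(cfg)
        intervals = detect_guidewire(pullback)
        for start, width in intervals:
            assert width > 0
            center = (start + width / 2.0) % 496
            assert abs(center - 115) <= 3

    def test_drifting_shadow_tracked(self):
        """Shadow moving 1 A-line per frame stays within ±3 of the truth."""
        cfg = PhantomConfig(
            n_frames=8, n_r=360, n_theta=496, lumen_radius_px=150.0,
            guidewire_width=30, wall_depth_px=200, speckle_shape=0.0, seed=5,
        )
        frames = []
        for z in range(cfg.n_frames):
            c = replace(cfg, n_frames=1, guidewire_center_theta=100 + z, seed=5 + z)
            pb, *_ = generate_pullback(c)
            frames.append(pb.frames[0])
        from octaline.data import PolarPullback

        intervals = detect_guidewire(PolarPullback(np.stack(frames)))
        for z, (start, width) in enumerate(intervals):
            center = (start + width / 2.0) % 496
            assert abs(center - (100 + z)) <= 3

    def test_no_shadow_returns_empty(self):
        cfg = PhantomConfig(
            n_frames=3, n_r=360, n_theta=96, lumen_radius_px=100.0,
            guidewire_width=0, wall_depth_px=230, seed=6,
        )
        pullback, *_ = generate_pullback(cfg)
        assert all(width == 0 for _, width in detect_guidewire(pullback))


class TestSegmentLumen:
    def segmentation_error(self, speckle, eccentricity):
        cfg = PhantomConfig(
            n_frames=1, eccentricity_amplitude=eccentricity, speckle_shape=speckle,
            guidewire_width=0, seed=9,
        )
        pullback, _, contours, _ = generate_pullback(cfg)
        contour = segment_lumen(pullback.frames[0])
        return np.abs(contour.boundary_r - contours[0].boundary_r).max()

    def test_noise_free_circle_within_2px(self):
        assert self.segmentation_error(speckle=0.0, eccentricity=0.0) <= 2.0

    def test_noise_free_eccentric_within_3px(self):
        assert self.segmentation_error(speckle=0.0, eccentricity=0.2) <= 3.0

    def test_default_speckle_within_5px(self):
        assert self.segmentation_error(speckle=4.0, eccentricity=0.05) <= 5.0

    def test_all_zero_frame_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            segment_lumen(np.zeros((400, 64)))

    def test_guidewire_alines_interpolated_and_flagged(self):
        cfg = PhantomConfig(
            n_frames=1, guidewire_center_theta=60, guidewire_width=24, seed=10,
            speckle_shape=0.0,
        )
        pullback, _, contours, _ = generate_pullback(cfg)
        contour = segment_lumen(pullback.frames[0], guidewire_interval=(48, 24))
        assert not contour.valid_mask[(48 + np.arange(24)) % 496].any()
        err = np.abs(contour.boundary_r - contours[0].boundary_r)
        assert err.max() <= 4.0  # interpolated sector stays near truth


class TestPixelShift:
    def test_boundary_sample_moves_to_index_zero(self, small_phantom, rng):
        _, pullback, _, contours, _ = small_phantom
        frame = pullback.frames[0]
        shifted, shifts = pixel_shift(frame, contours[0])
        for t in range(0, frame.shape[1], 7):
            assert shifted[0, t] == frame[shifts[t], t]

    def test_inverse_shift_round_trips_overlap(self, small_phantom):
        _, pullback, _, contours, _ = small_phantom
        frame = pullback.frames[0]
        shifted, shifts = pixel_shift(frame, contours[0])
        restored = inverse_pixel_shift(shifted, shifts)
        for t in range(frame.shape[1]):
            s = shifts[t]
            np.testing.assert_array_equal(restored[s:, t], frame[s:, t])

    def test_zero_contour_is_identity(self, rng):
        frame = rng.random((50, 32))
        shifted, _ = pixel_shift(frame, LumenContour(boundary_r=np.zeros(32)))
        np.testing.assert_array_equal(shifted, frame)

    def test_contour_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pixel_shift(rng.random((50, 32)), LumenContour(boundary_r=np.zeros(31)))


class TestCropAndDenoise:
    def test_full_size_input_yields_roi_shape(self):
        frame = np.random.default_rng(0).random((968, 496))
        out = crop_and_denoise(frame)
        assert out.roi.shape == (ROI_LENGTH, 496)
        assert out.data.shape == (KEEP_LENGTH, 496)
        assert out.pad_source.shape == (5, 496)

    def test_constant_input_unchanged(self):
        frame = np.full((300, 64), 1234.5)
        out = crop_and_denoise(frame)
        np.testing.assert_allclose(out.data, 1234.5)

    def test_impulse_response_is_normalized(self):
        frame = np.zeros((300, 64))
        frame[100, 32] = 1.0
        out = crop_and_denoise(frame)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            crop_and_denoise(np.zeros((150, 64)))
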