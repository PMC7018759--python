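"""Dense CRF: kernel values, mean-field limits, energy optimality, noise cleaning."""

import numpy as np
import pytest

from octaline.crf import (
    CrfParams,
    EnFaceCRF,
    choose_crf_params,
    crf_energy,
    exhaustive_min_energy_labels,
    mean_field_infer,
    smoothness_kernel,
)
from octaline.data import ALineLabel, EnFaceMap


def noisy_map(labels, noise_fraction, rng, confidence=0.85):
    """Probability map around a label grid with a fraction of cells flipped."""
    n_theta, n_frames = labels.shape
    noisy = labels.copy()
    n_flip = int(round(noise_fraction * labels.size))
    idx = rng.choice(labels.size, size=n_flip, replace=False)
    flat = noisy.ravel()
    flat[idx] = (flat[idx] + 1 + rng.integers(0, 2, n_flip)) % 3
    probs = np.full((n_theta, n_frames, 3), (1 - confidence) / 2)
    for l in range(3):
        probs[..., l][noisy == l] = confidence
    probs /= probs.sum(axis=-1, keepdims=True)
    return EnFaceMap(labels=noisy, probs=probs)


class TestSmoothnessKernel:
    def test_zero_distance_returns_weight(self):
        p = CrfParams(omega1=2.5, theta_alpha=3.0)
        assert smoothness_kernel((4, 4), (4, 4), p) == pytest.approx(2.5)

    def test_distance_sqrt2_theta_alpha_gives_e_minus_one(self):
        p = CrfParams(omega1=1.0, theta_alpha=3.0)
        d = 3.0 * np.sqrt(2.0)
        got = smoothness_kernel((0.0, 0.0), (d, 0.0), p)
        assert got == pytest.approx(np.exp(-1.0))

    def test_wrap_around_distance_is_one(self):
        p = CrfParams(omega1=1.0, theta_alpha=2.0)
        wrap = smoothness_kernel((0, 0), (495, 0), p, n_theta=496)
        near = smoothness_kernel((0, 0), (1, 0), p, n_theta=496)
        assert wrap == pytest.approx(near)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            CrfParams(theta_alpha=0.0)


class TestMeanField:
    def test_zero_weight_reduces_to_unary_argmax(self, rng):
        probs = rng.dirichlet([1, 1, 1], size=(12, 6))
        m = EnFaceMap(labels=probs.argmax(-1).astype(np.int8), probs=probs)
        out = mean_field_infer(m, CrfParams(omega1=0.0))
        np.testing.assert_array_equal(np.asarray(out.labels), probs.argmax(-1))

    def test_single_cell_island_suppressed(self):
        probs = np.full((7, 7, 3), 0.05)
        probs[..., 0] = 0.9
        probs[3, 3] = [0.2, 0.6, 0.2]
        probs /= probs.sum(-1, keepdims=True)
        m = EnFaceMap(labels=probs.argmax(-1).astype(np.int8), probs=probs)
        out = mean_field_infer(m, CrfParams(omega1=1.0, theta_alpha=3.0))
        assert out.labels[3, 3] == 0

    def test_uniform_input_stays_uniform(self):
        probs = np.full((6, 5, 3), 1.0 / 3.0)
        m = EnFaceMap(labels=np.zeros((6, 5)), probs=probs)
        out = mean_field_infer(m, CrfParams(omega1=1.0, theta_alpha=2.0))
        np.testing.assert_allclose(out.probs, 1.0 / 3.0, atol=1e-9)

    def test_unnormalized_rows_rejected(self):
        labels = np.zeros((4, 3), dtype=np.int8)
        m = EnFaceMap(labels=labels)
        m.probs = np.full((4, 3, 3), 0.5)  # bypass constructor check
        with pytest.raises(ValueError, match="normalized"):
            mean_field_infer(m, CrfParams())

    def test_guidewire_cells_keep_state(self, rng):
        probs = rng.dirichlet([1, 1, 1], size=(8, 4))
        labels = probs.argmax(-1).astype(np.int8)
        labels[2, :] = int(ALineLabel.GUIDEWIRE)
        m = EnFaceMap(labels=labels, probs=probs)
        out = mean_field_infer(m, CrfParams(omega1=1.5, theta_alpha=2.0))
        assert (out.labels[2, :] == int(ALineLabel.GUIDEWIRE)).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_energy_near_exhaustive_optimum_3x3(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet([1.5, 1.5, 1.5], size=(3, 3))
        params = CrfParams(omega1=0.8, theta_alpha=1.2, n_iterations=15)
        m = EnFaceMap(labels=probs.argmax(-1).astype(np.int8), probs=probs)
        out = mean_field_infer(m, params)
        e_mf = crf_energy(np.asarray(out.labels), probs, params)
        _, e_min = exhaustive_min_energy_labels(probs, params)
        assert e_mf <= 1.05 * e_min + 1e-9

    def test_label_changes_non_increasing_after_second_iteration(self, rng):
        labels = np.zeros((24, 16), dtype=np.int8)
        labels[5:12, 4:10] = 1
        m = noisy_map(labels, 0.15, rng)
        _, changes = mean_field_infer(
            m, CrfParams(omega1=1.5, theta_alpha=2.0, n_iterations=10),
            track_label_changes=True,
        )
        assert all(b <= a for a, b in zip(changes[1:-1], changes[2:]))


class TestNoiseCleaning:
    def test_smoothing_improves_mean_f1_at_ten_percent_noise(self, rng):
        """Injecting 10% label noise and smoothing must raise mean per-class
        F1 — the qualitative before/after effect of CRF noise cleaning."""
        from octaline.evaluation import confusion_metrics

        truth = np.full((48, 30), 2, dtype=np.int8)
        truth[5:20, 4:20] = 0
        truth[30:42, 12:26] = 1
        m = noisy_map(truth, 0.10, rng)
        before = confusion_metrics(np.asarray(m.labels), truth).mean_f1()
        out = mean_field_infer(m, CrfParams(omega1=1.0, theta_alpha=1.5))
        after = confusion_metrics(np.asarray(out.labels), truth).mean_f1()
        assert after > before


class TestParamChoice:
    def test_single_point_grid_returned(self, rng):
        truth = np.zeros((8, 6), dtype=np.int8)
        m = noisy_map(truth, 0.1, rng)
        only = CrfParams(omega1=1.0, theta_alpha=2.0)
        chosen, scores = choose_crf_params([(m, truth)], [only])
        assert chosen is only
        assert len(scores) == 1

    def test_choice_never_worse_than_no_smoothing(self, rng):
        truth = np.full((32, 20), 2, dtype=np.int8)
        truth[4:12, 3:12] = 0
        m = noisy_map(truth, 0.12, rng)
        crf = EnFaceCRF()
        crf.fit([(m, truth)])
        zero_idx = [i for i, p in enumerate(crf.grid) if p.omega1 == 0][0]
        assert max(crf.grid_scores_) == crf.grid_scores_[
            crf.grid_scores_.index(max(crf.grid_scores_))
        ]
        assert crf.grid_scores_[crf.grid.index(crf.params_)] >= crf.grid_scores_[zero_idx]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            choose_crf_params([], [])
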