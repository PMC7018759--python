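"""Dense-CRF smoothing of en-face (θ, z) A-line probability maps.

A-line classification treats each A-line independently, so isolated
misclassifications speckle the en-face map.  A fully connected conditional
random field over all (θ, z) grid cells, with Potts label compatibility and
a Gaussian *smoothness* pairwise kernel

    k(i, j) = ω₁ · exp(−|pᵢ − pⱼ|² / (2 θ_α²))

removes small isolated regions.  En-face cells carry no meaningful intensity,
so the appearance kernel of the usual two-kernel formulation is dropped
(ω₂ = 0); the data model retains ω₂/θ_β/θ_γ for completeness.

Inference is mean-field: unary potentials −log(p + ε) from the classifier's
probability map, iterated Gaussian message passing (circular in θ, linear in
z), softmax re-estimation, argmax labels at the end.  Guidewire cells are
masked out of message passing entirely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import ALineLabel, EnFaceMap

__all__ = [
    "CrfParams",
    "smoothness_kernel",
    "mean_field_infer",
    "crf_energy",
    "exhaustive_min_energy_labels",
    "choose_crf_params",
    "EnFaceCRF",
]

_EPS = 1e-6


@dataclass
class CrfParams:
    """Dense-CRF configuration.

    ``theta_alpha`` is the spatial scale in grid cells; ``anisotropy``
    optionally scales z separately (A-line pitch and frame pitch are
    physically different; by default both axes share ``theta_alpha``).
    ``omega2``/``theta_beta``/``theta_gamma`` belong to the appearance kernel
    and stay at 0 / unused in the conformant configuration.
    """

    omega1: float = 1.0
    theta_alpha: float = 2.0
    n_iterations: int = 10
    anisotropy: float = 1.0  # z scale = theta_alpha * anisotropy
    omega2: float = 0.0
    theta_beta: float = 1.0
    theta_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.theta_alpha <= 0:
            raise ValueError("theta_alpha must be positive")
        if self.omega1 < 0:
            raise ValueError("omega1 must be non-negative")


def _circ_delta(i: int, j: int, n: int) -> int:
    d = abs(i - j) % n
    return min(d, n - d)


def smoothness_kernel(
    p_i: tuple[float, float],
    p_j: tuple[float, float],
    params: CrfParams,
    n_theta: int | None = None,
) -> float:
    """Pairwise smoothness kernel between two (θ, z) grid positions.

    θ distance is circular when ``n_theta`` is given (A-line 0 is adjacent to
    A-line n_theta − 1); z distance is linear.  Symmetric in (i, j).
    """
    dt = p_i[0] - p_j[0]
    if n_theta is not None:
        dt = _circ_delta(int(p_i[0]), int(p_j[0]), n_theta)
    dz = (p_i[1] - p_j[1]) / max(params.anisotropy, 1e-12)
    d2 = float(dt) ** 2 + float(dz) ** 2
    return params.omega1 * float(np.exp(-d2 / (2.0 * params.theta_alpha**2)))


def _gaussian_weights(sigma: float) -> np.ndarray:
    """Unnormalized Gaussian tap weights exp(−d²/2σ²), k(0) = 1."""
    radius = max(int(np.ceil(3.0 * sigma)), 1)
    d = np.arange(-radius, radius + 1)
    return np.exp(-(d.astype(float) ** 2) / (2.0 * sigma**2))


def _smoothness_filter(q: np.ndarray, params: CrfParams) -> np.ndarray:
    """Separable unnormalized Gaussian filtering of Q, wrap in θ, nearest in z,
    with the self-contribution (k(i,i) = 1) removed."""
    w_theta = _gaussian_weights(params.theta_alpha)
    w_z = _gaussian_weights(params.theta_alpha * params.anisotropy)
    out = ndimage.correlate1d(q, w_theta, axis=0, mode="wrap")
    out = ndimage.correlate1d(out, w_z, axis=1, mode="constant", cval=0.0)
    return out - q


def mean_field_infer(
    enface: EnFaceMap, params: CrfParams, track_label_changes: bool = False
) -> EnFaceMap | tuple[EnFaceMap, list[int]]:
    """Mean-field inference on an en-face probability map.

    Returns a new :class:`EnFaceMap` with smoothed probabilities and argmax
    labels; guidewire cells are excluded from message passing and keep their
    state.  With ``track_label_changes`` the per-iteration count of label
    flips is also returned.
    """
    if enface.probs is None:
        raise ValueError("mean-field inference needs class probabilities")
    probs = np.asarray(enface.probs, dtype=float)
    gw = enface.guidewire_mask
    live = ~gw
    row_sums = probs.sum(axis=-1)
    if np.any(np.abs(row_sums[live] - 1.0) > 1e-3):
        raise ValueError("input probability rows are not normalized")

    unary = -np.log(np.clip(probs, _EPS, None))
    q = probs.copy()
    q[gw] = 0.0
    n_theta, n_frames, _ = q.shape
    tt, zz = np.meshgrid(np.arange(n_theta), np.arange(n_frames), indexing="ij")
    parity = (tt + zz) % 2
    labels_prev = np.argmax(q, axis=-1)
    changes: list[int] = []
    for _ in range(params.n_iterations):
        if params.omega1 == 0:
            break
        # red-black (checkerboard) schedule: each half-update sees the
        # freshest estimates of the other half, which settles mean field
        # where a fully parallel update can oscillate
        for par in (0, 1):
            message = np.stack(
                [_smoothness_filter(q[..., l], params) for l in range(q.shape[-1])],
                axis=-1,
            )
            # Potts compatibility: penalty for label l is the mass of other labels
            total = message.sum(axis=-1, keepdims=True)
            pairwise = params.omega1 * (total - message)
            logits = -unary - pairwise
            logits -= logits.max(axis=-1, keepdims=True)
            q_new = np.exp(logits)
            q_new /= q_new.sum(axis=-1, keepdims=True)
            update = (parity == par) & live
            q[update] = q_new[update]
        labels_now = np.argmax(q, axis=-1)
        changes.append(int(np.count_nonzero((labels_now != labels_prev) & live)))
        labels_prev = labels_now

    out_probs = q.copy()
    out_probs[gw] = 1.0 / q.shape[-1]  # placeholder; labels stay GUIDEWIRE
    labels = np.argmax(out_probs, axis=-1).astype(np.int8)
    labels[gw] = int(ALineLabel.GUIDEWIRE)
    result = EnFaceMap(labels=labels, probs=out_probs)
    if track_label_changes:
        return result, changes
    return result


# ---------------------------------------------------------------------------
# energy bookkeeping + exhaustive oracle (tiny grids)


def crf_energy(labels: np.ndarray, probs: np.ndarray, params: CrfParams) -> float:
    """Exact CRF energy of a labeling: Σ unary + Σ_{i<j} k(i,j)·[lᵢ ≠ lⱼ].

    θ is treated circularly.  Quadratic in grid size — for tests only.
    """
    labels = np.asarray(labels)
    n_theta, n_frames = labels.shape
    unary = -np.log(np.clip(probs, _EPS, None))
    cells = list(itertools.product(range(n_theta), range(n_frames)))
    energy = sum(float(unary[t, z, labels[t, z]]) for t, z in cells)
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            (ti, zi), (tj, zj) = cells[a], cells[b]
            if labels[ti, zi] != labels[tj, zj]:
                energy += smoothness_kernel((ti, zi), (tj, zj), params, n_theta=n_theta)
    return energy


def exhaustive_min_energy_labels(
    probs: np.ndarray, params: CrfParams
) -> tuple[np.ndarray, float]:
    """Brute-force minimum-energy labeling over all assignments (tiny grids)."""
    n_theta, n_frames, n_labels = probs.shape
    n_cells = n_theta * n_frames
    if n_labels**n_cells > 2_000_000:
        raise ValueError("grid too large for exhaustive enumeration")
    cells = list(itertools.product(range(n_theta), range(n_frames)))
    kernel = np.zeros((n_cells, n_cells))
    for a in range(n_cells):
        for b in range(a + 1, n_cells):
            kernel[a, b] = kernel[b, a] = smoothness_kernel(
                cells[a], cells[b], params, n_theta=n_theta
            )
    unary = -np.log(np.clip(probs, _EPS, None)).reshape(n_cells, n_labels)
    assignments = np.asarray(
        list(itertools.product(range(n_labels), repeat=n_cells)), dtype=np.int8
    )
    e_unary = unary[np.arange(n_cells)[None, :], assignments].sum(axis=1)
    disagree = assignments[:, :, None] != assignments[:, None, :]
    e_pair = 0.5 * (disagree * kernel[None, :, :]).sum(axis=(1, 2))
    energies = e_unary + e_pair
    best = int(np.argmin(energies))
    return assignments[best].reshape(n_theta, n_frames), float(energies[best])


# ---------------------------------------------------------------------------
# validation-driven parameter choice


def choose_crf_params(
    validation_maps: list[tuple[EnFaceMap, np.ndarray]],
    grid: list[CrfParams],
) -> tuple[CrfParams, list[float]]:
    """Grid-search CRF parameters maximizing mean per-class F1 on validation.

    ``validation_maps`` pairs each probability map with its reference label
    grid.  Ties keep the earliest grid entry, so putting ω₁ = 0 first
    guarantees the choice never scores below no smoothing.
    """
    from .evaluation import confusion_metrics

    if not grid:
        raise ValueError("empty CRF parameter grid")
    scores: list[float] = []
    for params in grid:
        f1s: list[float] = []
        for enface, reference in validation_maps:
            smoothed = mean_field_infer(enface, params)
            report = confusion_metrics(smoothed.labels, reference)
            f1s.extend(v["f1"] for v in report.per_class.values() if v["f1"] is not None)
        scores.append(float(np.mean(f1s)) if f1s else 0.0)
    return grid[int(np.argmax(scores))], scores


class EnFaceCRF(object):
    """Estimator-style wrapper: ``fit`` grid-searches parameters on
    validation maps, ``transform`` smooths new maps."""

    def __init__(self, grid: list[CrfParams] | None = None):
        if grid is None:
            grid = [CrfParams(omega1=0.0)] + [
                CrfParams(omega1=w, theta_alpha=a)
                for w in (0.5, 1.0, 2.0)
                for a in (1.5, 3.0)
            ]
        self.grid = grid

    def fit(self, validation_maps: list[tuple[EnFaceMap, np.ndarray]]):
        self.params_, self.grid_scores_ = choose_crf_params(validation_maps, self.grid)
        return self

    def transform(self, enface: EnFaceMap) -> EnFaceMap:
        if not hasattr(self, "params_"):
            raise RuntimeError("EnFaceCRF is not fitted")
        return mean_field_infer(enface, self.params_)
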