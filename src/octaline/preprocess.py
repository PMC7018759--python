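"""Polar-domain pre-processing: guidewire removal, lumen segmentation,
pixel shift, ROI crop and Gaussian denoising.

The lumen boundary is found per frame by dynamic programming over θ: the
radial image gradient is computed with a derivative-of-Gaussian along r, and
the closed contour with the highest cumulative edge strength, subject to a
maximum per-step radial jump, is taken as the boundary.  The guidewire shadow
is tracked across frames by a second dynamic program on the accumulated
(θ, z) intensity map, with a transition penalty that encodes the slow drift
of the shadow in θ.

After segmentation every A-line is shifted left so its boundary sits at
radial index 0, the first 200 px (~1 mm) are designated the region of
interest, and a 7 × 7, σ = 1 Gaussian filter suppresses speckle.  Five extra
radial samples (indices 200–204) are retained past the ROI: they are the
source for the right edge padding of the CNN input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .data import LumenContour, PolarPullback

__all__ = [
    "ROI_LENGTH",
    "PAD_SOURCE_LENGTH",
    "KEEP_LENGTH",
    "detect_guidewire",
    "segment_lumen",
    "pixel_shift",
    "inverse_pixel_shift",
    "crop_and_denoise",
    "optimal_closed_path",
    "track_minimum_path",
    "ProcessedFrame",
    "preprocess_pullback",
]

#: Radial extent of the tissue region of interest (~1 mm at 5 µm pitch).
ROI_LENGTH = 200
#: Samples retained past the ROI as the CNN right-padding source.
PAD_SOURCE_LENGTH = 5
KEEP_LENGTH = ROI_LENGTH + PAD_SOURCE_LENGTH


# ---------------------------------------------------------------------------
# guidewire shadow tracking


def _circular_distance(n: int) -> np.ndarray:
    """(n, n) matrix of circular index distances."""
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n - d)


def track_minimum_path(cost: np.ndarray, drift_penalty: float) -> np.ndarray:
    """Minimum-cost state sequence across frames with L1 drift penalty.

    ``cost`` is (n_frames, n_states); states are circular in θ.  Returns the
    state index per frame minimizing ``Σ cost[z, s_z] + λ Σ d(s_z, s_{z-1})``
    where d is circular distance.  Used to track the guidewire shadow center.
    """
    n_frames, n_states = cost.shape
    dist = _circular_distance(n_states)
    value = cost[0].copy()
    back = np.zeros((n_frames, n_states), dtype=np.int32)
    for z in range(1, n_frames):
        trans = value[None, :] + drift_penalty * dist  # [to, from]
        back[z] = np.argmin(trans, axis=1)
        value = cost[z] + np.min(trans, axis=1)
    path = np.empty(n_frames, dtype=np.int32)
    path[-1] = int(np.argmin(value))
    for z in range(n_frames - 1, 0, -1):
        path[z - 1] = back[z, path[z]]
    return path


def detect_guidewire(
    pullback: PolarPullback | np.ndarray,
    drift_penalty: float = 0.02,
    min_width: int = 3,
) -> list[tuple[int, int]]:
    """Locate the guidewire shadow sector per frame.

    Builds the accumulated intensity map (sum over r of each A-line), finds
    the shadow width from an Otsu threshold, and tracks the contiguous
    low-intensity interval across frames with :func:`track_minimum_path`.

    Returns a list of ``(start_theta, width)`` per frame; width 0 means no
    shadow was found (the mean accumulated intensity never dips below the
    adaptive threshold).  The drift penalty is expressed per A-line of center
    motion on the normalized intensity map.
    """
    frames = pullback.frames if isinstance(pullback, PolarPullback) else np.asarray(pullback)
    if frames.ndim != 3:
        raise ValueError("expected (n_frames, n_r, n_theta)")
    acc = frames.sum(axis=1)  # (n_frames, n_theta)
    n_frames, n_theta = acc.shape

    lo, hi = float(acc.min()), float(acc.max())
    if hi <= lo:
        return [(0, 0)] * n_frames
    norm = (acc - lo) / (hi - lo)
    try:
        thr = threshold_otsu(norm)
    except ValueError:
        return [(0, 0)] * n_frames
    below = norm < thr
    # a real shadow is near-zero along all of r, far darker than any tissue
    # A-line; Otsu splits any map, so require genuine contrast between sides
    if not below.any() or acc[below].mean() > 0.4 * acc[~below].mean():
        return [(0, 0)] * n_frames

    # shadow width: median circular run length of below-threshold columns
    widths = []
    for z in range(n_frames):
        runs = _circular_run_lengths(below[z])
        if runs:
            widths.append(max(runs))
    if not widths:
        return [(0, 0)] * n_frames
    width = int(np.median(widths))
    if width < min_width or width > n_theta // 2:
        warnings.warn("no plausible guidewire shadow found", stacklevel=2)
        return [(0, 0)] * n_frames

    # window-mean cost per candidate center, circular in θ
    kernel = np.ones(width) / width
    padded = np.concatenate([norm, norm[:, : width - 1]], axis=1)
    window_mean = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="valid"), 1, padded
    )  # [z, start]
    centers = track_minimum_path(window_mean, drift_penalty)
    return [(int(c), width) for c in centers]


def _circular_run_lengths(flags: np.ndarray) -> list[int]:
    if flags.all():
        return [flags.size]
    if not flags.any():
        return []
    # rotate so the sequence starts on a False
    start = int(np.argmin(flags))
    rolled = np.roll(flags, -start)
    runs, count = [], 0
    for f in rolled:
        if f:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def guidewire_mask(interval: tuple[int, int], n_theta: int) -> np.ndarray:
    """Boolean θ mask for a ``(start, width)`` interval (circular)."""
    mask = np.zeros(n_theta, dtype=bool)
    start, width = interval
    if width > 0:
        mask[(start + np.arange(width)) % n_theta] = True
    return mask


# ---------------------------------------------------------------------------
# lumen segmentation


def optimal_closed_path(
    score: np.ndarray,
    max_jump: int = 3,
    start_candidates: int | str = 5,
) -> np.ndarray:
    """Maximum-score closed path through a (n_theta, n_r) score grid.

    The path visits one radial index per θ, moves at most ``max_jump`` px per
    θ step, and closes circularly (the first and last rows are adjacent under
    the same jump constraint).  Closure is enforced by solving the dynamic
    program once per candidate start row and keeping the best closed path;
    ``start_candidates="all"`` makes the search exact over every start row.
    """
    score = np.asarray(score, dtype=float)
    n_theta, n_r = score.shape
    if n_theta < 2:
        return np.array([int(np.argmax(score[0]))])

    if start_candidates == "all":
        starts = np.arange(n_r)
    else:
        # seed from an unconstrained (open) solve plus the best first-row bins
        open_path = _open_dp(score, max_jump, start_row=None)
        k = int(start_candidates)
        top = np.argsort(score[0])[::-1][:k]
        starts = np.unique(np.concatenate([[open_path[0]], top]))

    best_total = -np.inf
    best_path: np.ndarray | None = None
    for r0 in starts:
        path, total = _closed_dp_from(score, max_jump, int(r0))
        if path is not None and total > best_total:
            best_total, best_path = total, path
    if best_path is None:  # no closed path exists (tiny pathological grids)
        return _open_dp(score, max_jump, start_row=None)
    return best_path


def _open_dp(score: np.ndarray, max_jump: int, start_row: int | None) -> np.ndarray:
    n_theta, n_r = score.shape
    value = np.full(n_r, -np.inf)
    if start_row is None:
        value[:] = score[0]
    else:
        value[start_row] = score[0, start_row]
    back = np.zeros((n_theta, n_r), dtype=np.int32)
    for t in range(1, n_theta):
        value, back[t] = _dp_step(value, score[t], max_jump)
    path = np.empty(n_theta, dtype=np.int64)
    path[-1] = int(np.argmax(value))
    for t in range(n_theta - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _closed_dp_from(
    score: np.ndarray, max_jump: int, r0: int
) -> tuple[np.ndarray | None, float]:
    n_theta, n_r = score.shape
    value = np.full(n_r, -np.inf)
    value[r0] = score[0, r0]
    back = np.zeros((n_theta, n_r), dtype=np.int32)
    for t in range(1, n_theta):
        value, back[t] = _dp_step(value, score[t], max_jump)
    lo, hi = max(r0 - max_jump, 0), min(r0 + max_jump + 1, n_r)
    window = value[lo:hi]
    if not np.isfinite(window).any():
        return None, -np.inf
    end = lo + int(np.argmax(window))
    path = np.empty(n_theta, dtype=np.int64)
    path[-1] = end
    for t in range(n_theta - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(value[end])


def _dp_step(prev: np.ndarray, row_score: np.ndarray, max_jump: int):
    """One θ step: best predecessor within ±max_jump for every radial index."""
    n_r = prev.size
    stacked = np.full((2 * max_jump + 1, n_r), -np.inf)
    for i, dr in enumerate(range(-max_jump, max_jump + 1)):
        src = np.roll(prev, dr)
        if dr > 0:
            src[:dr] = -np.inf
        elif dr < 0:
            src[dr:] = -np.inf
        stacked[i] = src
    choice = np.argmax(stacked, axis=0)
    best = stacked[choice, np.arange(n_r)]
    predecessor = np.arange(n_r) - (choice - max_jump)
    return best + row_score, predecessor.astype(np.int32)


def radial_edge_strength(frame: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Derivative-of-Gaussian gradient along r (positive at dark→bright)."""
    return ndimage.gaussian_filter1d(np.asarray(frame, dtype=float), sigma=sigma, axis=0, order=1)


def segment_lumen(
    frame: np.ndarray,
    guidewire_interval: tuple[int, int] | None = None,
    r_min: int = 25,
    r_max: int | None = None,
    max_jump: int = 3,
    gradient_sigma: float = 2.0,
    start_candidates: int | str = 5,
) -> LumenContour:
    """Segment the lumen boundary of one (r, θ) frame by dynamic programming.

    The search band ``[r_min, r_max)`` excludes the catheter sheath at small r
    and, by default, leaves ``KEEP_LENGTH`` samples beyond the boundary so the
    ROI and pad source exist after pixel shifting.  Guidewire A-lines get a
    neutral score, are bridged by linear interpolation afterwards, and are
    flagged invalid in the returned contour.
    """
    frame = np.asarray(frame, dtype=float)
    n_r, n_theta = frame.shape
    if frame.max() == frame.min():
        raise ValueError("degenerate input: frame has no intensity variation")
    if r_max is None:
        r_max = max(n_r - KEEP_LENGTH, r_min + 2)
    if r_max <= r_min:
        raise ValueError(f"empty search band [{r_min}, {r_max})")

    edge = radial_edge_strength(frame, sigma=gradient_sigma)
    score = edge[r_min:r_max, :].T.copy()  # (n_theta, band)

    gw = None
    if guidewire_interval is not None and guidewire_interval[1] > 0:
        gw = guidewire_mask(guidewire_interval, n_theta)
        score[gw, :] = 0.0

    path = optimal_closed_path(score, max_jump=max_jump, start_candidates=start_candidates)
    boundary = path.astype(float) + r_min

    valid = np.ones(n_theta, dtype=bool)
    if gw is not None and gw.any() and not gw.all():
        valid[gw] = False
        boundary = _interpolate_circular(boundary, valid)
    return LumenContour(boundary_r=boundary, valid_mask=valid)


def _interpolate_circular(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation across invalid spans on a circular index domain."""
    n = values.size
    idx = np.arange(n)
    good = idx[valid]
    # unwrap by tiling the valid samples one period to each side
    xp = np.concatenate([good - n, good, good + n])
    fp = np.tile(values[valid], 3)
    out = values.copy()
    out[~valid] = np.interp(idx[~valid], xp, fp)
    return out


# ---------------------------------------------------------------------------
# pixel shift + ROI


def pixel_shift(frame: np.ndarray, contour: LumenContour) -> tuple[np.ndarray, np.ndarray]:
    """Shift every A-line left so its lumen boundary sits at radial index 0.

    Returns ``(shifted, shifts)``; vacated samples at the right end are
    zero-filled and ``shifts`` (integer px per A-line) allows inverse mapping.
    """
    frame = np.asarray(frame)
    n_r, n_theta = frame.shape
    if contour.n_theta != n_theta:
        raise ValueError(f"contour has {contour.n_theta} A-lines, frame has {n_theta}")
    shifts = np.rint(contour.boundary_r).astype(int)
    shifted = np.zeros_like(frame, dtype=float)
    for t in range(n_theta):
        s = shifts[t]
        if s < n_r:
            shifted[: n_r - s, t] = frame[s:, t]
    return shifted, shifts


def inverse_pixel_shift(shifted: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Undo :func:`pixel_shift`; samples shifted out of range stay zero."""
    shifted = np.asarray(shifted)
    n_r, n_theta = shifted.shape
    out = np.zeros_like(shifted, dtype=float)
    for t in range(n_theta):
        s = int(shifts[t])
        if s < n_r:
            out[s:, t] = shifted[: n_r - s, t]
    return out


@dataclass
class ProcessedFrame:
    """Denoised, boundary-aligned frame: 200-px ROI + 5-px pad source."""

    data: np.ndarray  # (KEEP_LENGTH, n_theta)
    shifts: np.ndarray

    @property
    def roi(self) -> np.ndarray:
        return self.data[:ROI_LENGTH]

    @property
    def pad_source(self) -> np.ndarray:
        return self.data[ROI_LENGTH:KEEP_LENGTH]


def crop_and_denoise(
    shifted: np.ndarray, shifts: np.ndarray | None = None, sigma: float = 1.0
) -> ProcessedFrame:
    """Crop a pixel-shifted frame to ROI + pad source and Gaussian-filter it.

    Keeps radial indices [0, 205): [0, 200) is the region of interest, the
    remaining five samples feed the CNN right padding.  The filter is the
    7 × 7, σ = 1 normalized Gaussian with reflect boundary handling.
    """
    shifted = np.asarray(shifted, dtype=float)
    if shifted.shape[0] < KEEP_LENGTH:
        raise ValueError(
            f"need ≥ {KEEP_LENGTH} radial samples after shifting, got {shifted.shape[0]}"
        )
    kept = shifted[:KEEP_LENGTH]
    # footprint (7, 7) → truncate at 3 px for σ = 1
    smooth = ndimage.gaussian_filter(kept, sigma=sigma, truncate=3.0 / sigma, mode="reflect")
    if shifts is None:
        shifts = np.zeros(shifted.shape[1], dtype=int)
    return ProcessedFrame(data=smooth, shifts=np.asarray(shifts))


# ---------------------------------------------------------------------------
# pullback-level convenience


def preprocess_pullback(
    pullback: PolarPullback,
    r_min: int = 25,
    use_contours: list[LumenContour] | None = None,
) -> tuple[list[ProcessedFrame], list[LumenContour], list[tuple[int, int]]]:
    """Run the full pre-processing chain on every frame of a pullback.

    Returns (processed frames, lumen contours, guidewire intervals).  If
    ``use_contours`` is given, segmentation is skipped and the provided
    contours (e.g. phantom ground truth) are used for the shift.
    """
    intervals = detect_guidewire(pullback)
    processed: list[ProcessedFrame] = []
    contours: list[LumenContour] = []
    for z in range(pullback.n_frames):
        frame = pullback.frames[z]
        if use_contours is not None:
            contour = use_contours[z]
        else:
            contour = segment_lumen(frame, guidewire_interval=intervals[z], r_min=r_min)
        shifted, shifts = pixel_shift(frame, contour)
        processed.append(crop_and_denoise(shifted, shifts))
        contours.append(contour)
    return processed, contours, intervals
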