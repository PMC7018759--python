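"""Hand-crafted lumen-morphology features.

Pixel shifting normalizes lesion appearance for the CNN but erases the shape
of the lumen border — which is exactly where large calcifications show up
(flat or irregular walls).  These features recover that information from the
segmented contour alone; they are a pure function of lumen geometry and never
touch image intensities.

Five feature families are computed, each with the current-frame value and its
change across the adjacent ±3 frames where applicable:

* frame lumen area (shoelace polygon area, mm²) with deltas and ratios;
* frame eccentricity of the moment ellipse, with deltas;
* per-A-line signed distance to the equal-area concentric circle centered at
  the lumen centroid (positive outward), with local window aggregates;
* best-fit lines over sliding circular windows of 1/8 of the boundary points
  (total-least-squares): sum of squared perpendicular residuals, goodness of
  fit R², and line magnitude (chord length projected on the fitted line),
  per-A-line and as frame-level min/max/mean with deltas;
* per-A-line r-θ lumen slope (central difference after 5-tap smoothing) —
  slope 0 means perpendicular beam incidence — with |slope| window aggregates.

The historical feature inventory this package descends from counted 371
scalars; here the families are parameterized and the manifest records the
realized count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LumenContour

__all__ = [
    "lumen_area",
    "contour_xy",
    "frame_eccentricity",
    "aline_signed_distance",
    "fit_lumen_lines",
    "lumen_slope",
    "MorphConfig",
    "MorphologyFeatureExtractor",
]


def contour_xy(contour: LumenContour, radial_pitch_mm: float = 1.0) -> np.ndarray:
    """(n_theta, 2) Cartesian boundary points, catheter center at the origin."""
    thetas = 2 * np.pi * np.arange(contour.n_theta) / contour.n_theta
    r = contour.boundary_r * radial_pitch_mm
    return np.stack([r * np.cos(thetas), r * np.sin(thetas)], axis=-1)


def _polygon_moments(xy: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed area, centroid, and central second moments of a closed polygon."""
    x, y = xy[:, 0], xy[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        raise ValueError("degenerate contour: zero enclosed area")
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    # second moments about the origin (standard polygon formulas)
    ixx = ((y * y + y * yn + yn * yn) * cross).sum() / 12.0
    iyy = ((x * x + x * xn + xn * xn) * cross).sum() / 12.0
    ixy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / 24.0
    # shift to centroid, normalize by area → covariance of the uniform region
    cov = np.array(
        [
            [iyy / area - cx * cx, ixy / area - cx * cy],
            [ixy / area - cx * cy, ixx / area - cy * cy],
        ]
    )
    return float(abs(area)), np.array([cx, cy]), cov


def lumen_area(contour: LumenContour, radial_pitch_mm: float = 1.0) -> float:
    """Polygon (shoelace) area of the lumen boundary, in mm² when calibrated."""
    if np.count_nonzero(contour.valid_mask) < 3:
        raise ValueError("need at least 3 valid boundary points")
    area, _, _ = _polygon_moments(contour_xy(contour, radial_pitch_mm))
    return area


def frame_eccentricity(contour: LumenContour) -> float:
    """Eccentricity of the moment (best-fit) ellipse: sqrt(1 − (b/a)²) ∈ [0, 1)."""
    _, _, cov = _polygon_moments(contour_xy(contour))
    evals = np.linalg.eigvalsh(cov)
    evals = np.clip(evals, 0.0, None)
    if evals[1] <= 0:
        raise ValueError("degenerate contour: zero-extent moment ellipse")
    ratio2 = evals[0] / evals[1]  # (minor/major)² of the moment ellipse
    return float(np.sqrt(1.0 - ratio2))


def aline_signed_distance(contour: LumenContour) -> np.ndarray:
    """Signed distance of each boundary point to the equal-area circle.

    The circle shares the lumen's center of mass and area (R = sqrt(A/π));
    the distance is measured from the centroid along the ray through each
    boundary point, positive outward.
    """
    xy = contour_xy(contour)
    area, centroid, _ = _polygon_moments(xy)
    radius = np.sqrt(area / np.pi)
    return np.linalg.norm(xy - centroid, axis=1) - radius


def fit_lumen_lines(
    contour: LumenContour, n_windows_divisor: int = 8
) -> dict[str, np.ndarray]:
    """Total-least-squares line fits on sliding circular boundary windows.

    Windows hold ``⌊n_theta / n_windows_divisor⌋`` consecutive boundary
    points (1/8 of the border by default), one window centered on every
    A-line.  Per window: ``ssr`` — sum of squared perpendicular residuals;
    ``r2`` — 1 − SSR / total variance about the window centroid; ``magnitude``
    — chord between window endpoints projected on the fitted line.
    """
    n = contour.n_theta
    w = n // n_windows_divisor
    if w < 3:
        raise ValueError(f"window of {w} points is too small to fit a line")
    xy = contour_xy(contour)
    half = w // 2
    offsets = np.arange(w) - half
    idx = (np.arange(n)[:, None] + offsets[None, :]) % n
    pts = xy[idx]  # (n, w, 2)
    centroid = pts.mean(axis=1, keepdims=True)
    centered = pts - centroid
    cov = np.einsum("nwi,nwj->nij", centered, centered) / w
    evals, evecs = np.linalg.eigh(cov)  # ascending
    direction = evecs[:, :, 1]
    normal = evecs[:, :, 0]
    resid = np.einsum("nwi,ni->nw", centered, normal)
    ssr = (resid**2).sum(axis=1)
    total = (centered**2).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(total > 0, 1.0 - ssr / total, 1.0)
    chord = pts[:, -1] - pts[:, 0]
    magnitude = np.abs(np.einsum("ni,ni->n", chord, direction))
    return {"ssr": ssr, "r2": r2, "magnitude": magnitude}


def lumen_slope(contour: LumenContour, smooth_taps: int = 5) -> np.ndarray:
    """Per-A-line dR/dθ-index on the circular domain (5-tap smoothed).

    Zero slope means the beam hits the wall perpendicularly; large magnitudes
    flag oblique incidence, where superficial signal attenuation can mimic
    plaque.
    """
    r = contour.boundary_r
    n = r.size
    if smooth_taps > 1:
        kernel = np.ones(smooth_taps) / smooth_taps
        r = np.convolve(np.concatenate([r[-smooth_taps:], r, r[:smooth_taps]]), kernel, mode="same")[
            smooth_taps : smooth_taps + n
        ]
    return (np.roll(r, -1) - np.roll(r, 1)) / 2.0


# ---------------------------------------------------------------------------
# assembly


@dataclass
class MorphConfig:
    """Parameters of the morphology feature families."""

    delta_lags: tuple = (1, 2, 3)
    n_windows_divisor: int = 8
    local_window: int = 15  # A-lines for signed-distance / slope aggregates
    radial_pitch_mm: float = 0.005


@dataclass
class _FrameGeometry:
    area: float
    eccentricity: float
    signed_distance: np.ndarray
    lines: dict[str, np.ndarray]
    slope: np.ndarray


def _local_aggregates(values: np.ndarray, window: int) -> dict[str, np.ndarray]:
    half = window // 2
    idx = (np.arange(values.size)[:, None] + (np.arange(window) - half)[None, :]) % values.size
    block = values[idx]
    return {
        "mean": block.mean(axis=1),
        "min": block.min(axis=1),
        "max": block.max(axis=1),
    }


class MorphologyFeatureExtractor:
    """Assembles per-A-line morphology feature vectors for a whole pullback.

    The extractor consumes only lumen contours (one per frame) — never image
    intensities — so the features survive pixel shifting by construction.
    Frame-level families are shared by every A-line of a frame; ±k-frame
    deltas clamp at the pullback edges and a validity-flag feature records
    the clamp.
    """

    def __init__(self, config: MorphConfig | None = None):
        self.config = config or MorphConfig()
        self._names: list[str] | None = None

    def _frame_geometry(self, contour: LumenContour) -> _FrameGeometry:
        cfg = self.config
        return _FrameGeometry(
            area=lumen_area(contour, cfg.radial_pitch_mm),
            eccentricity=frame_eccentricity(contour),
            signed_distance=aline_signed_distance(contour),
            lines=fit_lumen_lines(contour, cfg.n_windows_divisor),
            slope=lumen_slope(contour),
        )

    def transform_pullback(self, contours: list[LumenContour]) -> np.ndarray:
        """Feature matrix of shape (n_theta * n_frames, n_features), A-line
        order θ-major within frame, frames in pullback order."""
        geoms = [self._frame_geometry(c) for c in contours]
        blocks = [self._frame_features(geoms, z) for z in range(len(geoms))]
        return np.concatenate(blocks, axis=0)

    def _frame_features(self, geoms: list[_FrameGeometry], z: int) -> np.ndarray:
        cfg = self.config
        n_frames = len(geoms)
        g = geoms[z]
        n_theta = g.signed_distance.size
        names: list[str] = []
        frame_scalars: list[float] = []

        def scalar(name: str, value: float) -> None:
            names.append(name)
            frame_scalars.append(float(value))

        # frame area family
        scalar("area", g.area)
        clamped = False
        for lag in cfg.delta_lags:
            for sign, tag in ((-1, "m"), (+1, "p")):
                zz = min(max(z + sign * lag, 0), n_frames - 1)
                clamped |= zz != z + sign * lag
                other = geoms[zz]
                scalar(f"area_delta_{tag}{lag}", g.area - other.area)
                scalar(f"area_ratio_{tag}{lag}", g.area / other.area)

        # eccentricity family
        scalar("eccentricity", g.eccentricity)
        for lag in cfg.delta_lags:
            for sign, tag in ((-1, "m"), (+1, "p")):
                zz = min(max(z + sign * lag, 0), n_frames - 1)
                scalar(f"ecc_delta_{tag}{lag}", g.eccentricity - geoms[zz].eccentricity)

        # best-fit-line frame aggregates + deltas
        line_aggs: dict[str, float] = {}
        for key in ("ssr", "r2", "magnitude"):
            arr = g.lines[key]
            for agg, fn in (("min", np.min), ("max", np.max), ("mean", np.mean)):
                line_aggs[f"line_{key}_{agg}"] = float(fn(arr))
        for name, value in line_aggs.items():
            scalar(name, value)
        for lag in cfg.delta_lags:
            for sign, tag in ((-1, "m"), (+1, "p")):
                zz = min(max(z + sign * lag, 0), n_frames - 1)
                other = geoms[zz]
                for key in ("ssr", "r2", "magnitude"):
                    for agg, fn in (("min", np.min), ("max", np.max), ("mean", np.mean)):
                        scalar(
                            f"line_{key}_{agg}_delta_{tag}{lag}",
                            line_aggs[f"line_{key}_{agg}"] - float(fn(other.lines[key])),
                        )

        scalar("edge_clamped", 1.0 if clamped else 0.0)

        # per-A-line families
        per_aline: list[tuple[str, np.ndarray]] = [("signed_distance", g.signed_distance)]
        for agg, arr in _local_aggregates(g.signed_distance, cfg.local_window).items():
            per_aline.append((f"signed_distance_{agg}", arr))
        for key in ("ssr", "r2", "magnitude"):
            per_aline.append((f"line_{key}", g.lines[key]))
        per_aline.append(("slope", g.slope))
        abs_aggs = _local_aggregates(np.abs(g.slope), cfg.local_window)
        per_aline.append(("abs_slope_mean", abs_aggs["mean"]))
        per_aline.append(("abs_slope_max", abs_aggs["max"]))

        names.extend(name for name, _ in per_aline)
        if self._names is None:
            self._names = names
        block = np.empty((n_theta, len(names)))
        n_scalar = len(frame_scalars)
        block[:, :n_scalar] = np.asarray(frame_scalars)[None, :]
        for j, (_, arr) in enumerate(per_aline):
            block[:, n_scalar + j] = arr
        return block

    @property
    def feature_names(self) -> list[str]:
        if self._names is None:
            raise RuntimeError("extract features at least once to realize names")
        return list(self._names)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def manifest(self) -> dict:
        return {
            "delta_lags": list(self.config.delta_lags),
            "n_windows_divisor": self.config.n_windows_divisor,
            "local_window": self.config.local_window,
            "n_features": self.n_features,
            "feature_names": self.feature_names,
        }
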