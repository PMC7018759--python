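"""Core data model for polar-domain IVOCT pullbacks.

Intravascular OCT acquires one radial intensity profile (an *A-line*) per
emitter angle; a frame is the (r, θ) stack of A-lines for one rotation, and a
pullback is the ordered stack of frames acquired while the catheter retracts
along the vessel axis z.  All computation in this package stays in the polar
domain; Cartesian (x, y) views are for display only.

Conventions: 0-based indices everywhere; the θ index increases
counter-clockwise; the r index increases away from the catheter; frames are
ordered distal → proximal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "ALineLabel",
    "PixelLabel",
    "PolarPullback",
    "LumenContour",
    "EnFaceMap",
    "FoldSplit",
    "pixel_labels_to_aline_label",
    "pixel_mask_to_aline_labels",
    "MIN_PLAQUE_PIXELS",
]


class ALineLabel(IntEnum):
    """Per-A-line tissue class.

    ``GUIDEWIRE`` is a mask state, not a tissue class: guidewire-shadow
    A-lines never enter training and are excluded from every confusion count.
    """

    FIBROLIPIDIC = 0
    FIBROCALCIFIC = 1
    OTHER = 2
    GUIDEWIRE = 3


#: The three tissue classes, in probability-vector order.
TISSUE_LABELS = (
    ALineLabel.FIBROLIPIDIC,
    ALineLabel.FIBROCALCIFIC,
    ALineLabel.OTHER,
)


class PixelLabel(IntEnum):
    """Per-pixel annotation classes for (r, θ) frames."""

    BACKGROUND = 0
    LUMEN = 1
    LIPID = 2
    CALCIUM = 3
    OTHER_TISSUE = 4


#: An A-line is called plaque only if it holds at least this many plaque pixels.
MIN_PLAQUE_PIXELS = 3


def pixel_labels_to_aline_label(mask_column: np.ndarray) -> ALineLabel:
    """Collapse one A-line's pixel annotation column to an A-line label.

    An A-line containing at least :data:`MIN_PLAQUE_PIXELS` lipid or calcium
    pixels is labeled by whichever of those two classes is in the majority;
    every other A-line is ``OTHER``.  A tie with both classes at or above the
    threshold is resolved to ``FIBROCALCIFIC`` (calcium drives interventional
    decisions, and the rule must be deterministic).

    Parameters
    ----------
    mask_column:
        1-D integer array of :class:`PixelLabel` values for one A-line.
    """
    col = np.asarray(mask_column)
    n_lipid = int(np.count_nonzero(col == PixelLabel.LIPID))
    n_calc = int(np.count_nonzero(col == PixelLabel.CALCIUM))
    if n_lipid >= MIN_PLAQUE_PIXELS and n_lipid > n_calc:
        return ALineLabel.FIBROLIPIDIC
    if n_calc >= MIN_PLAQUE_PIXELS and n_calc >= n_lipid:
        return ALineLabel.FIBROCALCIFIC
    return ALineLabel.OTHER


def pixel_mask_to_aline_labels(mask: np.ndarray) -> np.ndarray:
    """Vectorized :func:`pixel_labels_to_aline_label` over a full (r, θ) mask.

    Returns an ``(n_theta,)`` array of :class:`ALineLabel` codes.
    """
    mask = np.asarray(mask)
    n_lipid = np.count_nonzero(mask == PixelLabel.LIPID, axis=0)
    n_calc = np.count_nonzero(mask == PixelLabel.CALCIUM, axis=0)
    out = np.full(mask.shape[1], int(ALineLabel.OTHER), dtype=np.int8)
    fl = (n_lipid >= MIN_PLAQUE_PIXELS) & (n_lipid > n_calc)
    fc = (n_calc >= MIN_PLAQUE_PIXELS) & (n_calc >= n_lipid)
    out[fl] = int(ALineLabel.FIBROLIPIDIC)
    out[fc] = int(ALineLabel.FIBROCALCIFIC)
    return out


@dataclass
class PolarPullback:
    """An ordered stack of polar (r, θ) frames with physical calibration.

    Attributes
    ----------
    frames:
        ``(n_frames, n_r, n_theta)`` floating-point intensity array in the
        16-bit range (values are never rescaled on read).
    radial_pitch_mm:
        mm per radial pixel (~0.005, so 200 px ≈ 1 mm).
    pullback_speed_mm_s, frame_rate_fps:
        acquisition parameters; their ratio is the frame interval.
    """

    frames: np.ndarray
    radial_pitch_mm: float = 0.005
    pullback_speed_mm_s: float = 36.0
    frame_rate_fps: float = 180.0
    voi_id: str = "voi-0"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, n_r, n_theta); got {self.frames.shape}"
            )
        if self.n_theta < 16:
            raise ValueError(f"n_theta must be >= 16, got {self.n_theta}")
        if self.frame_interval_mm <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_r(self) -> int:
        return self.frames.shape[1]

    @property
    def n_theta(self) -> int:
        return self.frames.shape[2]

    @property
    def frame_interval_mm(self) -> float:
        """Pullback distance between consecutive frames (speed / frame rate)."""
        return self.pullback_speed_mm_s / self.frame_rate_fps


@dataclass
class LumenContour:
    """Per-A-line radial index of the lumen boundary for one frame.

    ``valid_mask`` is ``False`` where the boundary is interpolated through the
    guidewire shadow rather than measured.
    """

    boundary_r: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.boundary_r = np.asarray(self.boundary_r, dtype=float)
        if self.boundary_r.ndim != 1:
            raise ValueError("boundary_r must be 1-D")
        if np.any(self.boundary_r < 0):
            raise ValueError("boundary_r must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.boundary_r.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.boundary_r.shape:
                raise ValueError("valid_mask length must equal n_theta")

    @property
    def n_theta(self) -> int:
        return self.boundary_r.shape[0]


@dataclass
class EnFaceMap:
    """(θ, z) grid of per-A-line labels, optionally with class probabilities.

    ``labels`` has shape ``(n_theta, n_frames)`` with :class:`ALineLabel`
    codes; ``probs``, when present, has shape ``(n_theta, n_frames, 3)`` with
    rows summing to 1 over the three tissue classes.  Guidewire cells keep the
    ``GUIDEWIRE`` code regardless of ``probs``.
    """

    labels: np.ndarray
    probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be (n_theta, n_frames)")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != self.labels.shape + (3,):
                raise ValueError(
                    f"probs shape {self.probs.shape} does not match labels "
                    f"{self.labels.shape} + (3,)"
                )
            row_sums = self.probs.sum(axis=-1)
            gw = self.guidewire_mask
            if np.any(np.abs(row_sums[~gw] - 1.0) > 1e-6):
                raise ValueError("probability rows must sum to 1")

    @property
    def n_theta(self) -> int:
        return self.labels.shape[0]

    @property
    def n_frames(self) -> int:
        return self.labels.shape[1]

    @property
    def guidewire_mask(self) -> np.ndarray:
        return self.labels == int(ALineLabel.GUIDEWIRE)

    def relabel_from_probs(self) -> None:
        """Set labels to argmax of probabilities outside the guidewire mask."""
        if self.probs is None:
            raise ValueError("map carries no probabilities")
        gw = self.guidewire_mask
        new = np.argmax(self.probs, axis=-1).astype(np.int8)
        new[gw] = int(ALineLabel.GUIDEWIRE)
        self.labels = new


@dataclass
class FoldSplit:
    """VOI-granularity cross-validation split.

    Each fold maps VOI ids to train / validation / test roles; ``held_out``
    VOIs are untouched by every fold.  Every pooled VOI appears in a test set
    exactly once across folds.
    """

    folds: list[dict[str, list[str]]] = field(default_factory=list)
    held_out: list[str] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def validate(self) -> None:
        pooled: set[str] = set()
        for fold in self.folds:
            train, val, test = (
                set(fold["train"]),
                set(fold["validation"]),
                set(fold["test"]),
            )
            if train & val or train & test or val & test:
                raise ValueError("train/validation/test overlap within a fold")
            pooled |= train | val | test
        if pooled & set(self.held_out):
            raise ValueError("held-out VOIs appear in folds")
        tested = [v for fold in self.folds for v in fold["test"]]
        if sorted(tested) != sorted(pooled):
            raise ValueError("each pooled VOI must be tested exactly once")
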