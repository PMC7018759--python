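"""Readers and writers for pullbacks, masks, contours and en-face maps.

The canonical pullback container is a multi-page TIFF (16-bit gray, one page
per frame) with a JSON sidecar carrying the calibration:
``{n_r, n_theta, n_frames, dtype, radial_pitch_mm, pullback_speed_mm_s,
frame_rate_fps, voi_id}``.  A raw little-endian binary with the same sidecar
is accepted as a fallback dialect.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .data import ALineLabel, EnFaceMap, LumenContour, PolarPullback

__all__ = [
    "read_pullback",
    "write_pullback",
    "read_mask_stack",
    "write_mask_stack",
    "read_contours",
    "write_contours",
    "read_enface_csv",
    "write_enface",
    "ENFACE_PALETTE",
]

#: En-face rendering palette: green = fibrolipidic, red = fibrocalcific,
#: blue = other, white = guidewire.
ENFACE_PALETTE = {
    int(ALineLabel.FIBROLIPIDIC): (0, 176, 80),
    int(ALineLabel.FIBROCALCIFIC): (220, 30, 30),
    int(ALineLabel.OTHER): (40, 70, 220),
    int(ALineLabel.GUIDEWIRE): (255, 255, 255),
}

_CALIBRATION_KEYS = (
    "radial_pitch_mm",
    "pullback_speed_mm_s",
    "frame_rate_fps",
    "voi_id",
)


class FormatError(ValueError):
    """Raised when a payload disagrees with its sidecar or is malformed."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_pullback(pullback: PolarPullback, path: str | Path) -> Path:
    """Write a pullback as multi-page TIFF + JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = np.clip(np.rint(pullback.frames), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(path, frames.astype(np.uint16))
    sidecar = {
        "n_r": pullback.n_r,
        "n_theta": pullback.n_theta,
        "n_frames": pullback.n_frames,
        "dtype": "uint16",
        "radial_pitch_mm": pullback.radial_pitch_mm,
        "pullback_speed_mm_s": pullback.pullback_speed_mm_s,
        "frame_rate_fps": pullback.frame_rate_fps,
        "voi_id": pullback.voi_id,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_pullback(path: str | Path, calibration: dict | None = None) -> PolarPullback:
    """Read a pullback from a multi-page TIFF or raw binary + JSON sidecar.

    Frames are loaded in acquisition order and widened to float64 internally
    without rescaling.  ``calibration`` overrides sidecar fields.

    Raises
    ------
    FormatError
        On dimension mismatch between sidecar and payload, or a truncated /
        unreadable payload.
    """
    path = Path(path)
    sidecar: dict = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    if calibration:
        sidecar.update(calibration)

    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - wrap any decode failure
            raise FormatError(f"cannot decode TIFF {path}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
    else:
        for key in ("n_r", "n_theta", "n_frames", "dtype"):
            if key not in sidecar:
                raise FormatError(f"raw payload requires sidecar key {key!r}")
        shape = (sidecar["n_frames"], sidecar["n_r"], sidecar["n_theta"])
        raw = np.fromfile(path, dtype=np.dtype(sidecar["dtype"]))
        if raw.size != int(np.prod(shape)):
            raise FormatError(
                f"payload holds {raw.size} samples, sidecar implies {np.prod(shape)}"
            )
        frames = raw.reshape(shape)

    for key, dim in (("n_frames", 0), ("n_r", 1), ("n_theta", 2)):
        if key in sidecar and sidecar[key] != frames.shape[dim]:
            raise FormatError(
                f"sidecar {key}={sidecar[key]} but payload has {frames.shape[dim]}"
            )

    kwargs = {k: sidecar[k] for k in _CALIBRATION_KEYS if k in sidecar}
    pb = PolarPullback(frames.astype(np.float64), **kwargs)
    if pb.n_frames < 7:
        import warnings

        warnings.warn(
            f"pullback {pb.voi_id} has {pb.n_frames} frames; "
            "±3-frame morphology deltas will clamp",
            stacklevel=2,
        )
    return pb


def write_mask_stack(mask: np.ndarray, path: str | Path) -> Path:
    """Write a (n_frames, n_r, n_theta) annotation stack as 8-bit TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path


def read_mask_stack(path: str | Path) -> np.ndarray:
    mask = tifffile.imread(Path(path))
    if mask.ndim == 2:
        mask = mask[None]
    return mask.astype(np.uint8)


def write_contours(contours: list[LumenContour], path: str | Path) -> Path:
    """Serialize per-frame contours as CSV (frame, θ index, boundary_r, valid)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "theta", "boundary_r", "valid"])
        for z, contour in enumerate(contours):
            for t in range(contour.n_theta):
                writer.writerow(
                    [z, t, f"{contour.boundary_r[t]:.3f}", int(contour.valid_mask[t])]
                )
    return path


def read_contours(path: str | Path) -> list[LumenContour]:
    rows: dict[int, list[tuple[int, float, bool]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(int(rec["frame"]), []).append(
                (int(rec["theta"]), float(rec["boundary_r"]), bool(int(rec["valid"])))
            )
    contours = []
    for z in sorted(rows):
        rows[z].sort()
        contours.append(
            LumenContour(
                boundary_r=np.array([r for _, r, _ in rows[z]]),
                valid_mask=np.array([v for _, _, v in rows[z]]),
            )
        )
    return contours


def write_enface(enface: EnFaceMap, path: str | Path) -> tuple[Path, Path]:
    """Write an en-face map as a label CSV (θ rows, z columns) and a color PNG.

    Returns the (csv_path, png_path) pair.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    csv_path = path.with_suffix(".csv")
    png_path = path.with_suffix(".png")
    np.savetxt(csv_path, enface.labels, fmt="%d", delimiter=",")

    rgb = np.zeros((enface.n_theta, enface.n_frames, 3), dtype=np.uint8)
    for code, color in ENFACE_PALETTE.items():
        rgb[enface.labels == code] = color
    Image.fromarray(rgb).save(png_path)
    return csv_path, png_path


def read_enface_csv(path: str | Path) -> EnFaceMap:
    labels = np.loadtxt(Path(path), dtype=int, delimiter=",", ndmin=2)
    return EnFaceMap(labels=labels)
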