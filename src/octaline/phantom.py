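"""Synthetic polar-domain IVOCT phantoms with known ground truth.

The generator emulates the gross appearance of coronary OCT in (r, θ):

* a dark lumen bounded by a bright vessel wall, with circular-to-eccentric
  geometry and optional flattening across calcified spans (large
  calcifications tend to flatten the lumen wall);
* per-tissue A-line depth profiles — fibrous tissue decays slowly with depth;
  lipid pools appear as a bright cap followed by a steep exponential decay
  with a diffuse rear border (light is absorbed rapidly in lipid); calcium
  appears as a signal-poor pocket with sharp front and rear borders and
  preserved signal behind;
* a guidewire shadow sector (near-zero signal with a faint reflection at the
  catheter sheath radius) and a bright catheter sheath ring near r = 0;
* multiplicative gamma speckle.

It does not attempt physical wave simulation, polarization, motion or NURD
artifacts; its role is to give every downstream stage a ground truth that is
exactly consistent between pixel masks, lumen contours, and A-line labels.

A configurable fraction of calcium lesions is rendered with a "diffuse"
appearance that mimics lipid attenuation while still flattening the lumen.
On those A-lines the intensity profile is ambiguous and only lumen-shape
information separates the classes — the situation the hybrid
convolutional + morphology classifier exists for.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import (
    ALineLabel,
    FoldSplit,
    LumenContour,
    PixelLabel,
    PolarPullback,
    pixel_mask_to_aline_labels,
)

__all__ = [
    "TissueAppearance",
    "Lesion",
    "PhantomConfig",
    "generate_pullback",
    "generate_dataset",
    "default_voi_mix",
    "sample_voi_config",
    "SyntheticDataset",
]


@dataclass
class TissueAppearance:
    """Surface intensity (16-bit counts) and attenuation (per radial px).

    With the default 0.005 mm radial pitch, attenuation per px of 0.015 / 0.06
    corresponds to ~3 / ~12 mm^-1 — the contrast between fibrous and lipidous
    tissue that the classifier must learn.  Calcium interiors backscatter
    weakly and attenuate little, so signal behind a calcification survives.
    """

    fibrous_intensity: float = 24000.0
    fibrous_attenuation: float = 0.015
    lipid_intensity: float = 30000.0
    lipid_attenuation: float = 0.060
    calcium_intensity_factor: float = 0.12
    calcium_attenuation: float = 0.006
    behind_calcium_factor: float = 0.8
    ambiguous_intensity: float = 26000.0
    ambiguous_attenuation: float = 0.045
    lumen_floor: float = 200.0
    shadow_floor: float = 100.0
    sheath_intensity: float = 20000.0
    sheath_reflection_in_shadow: float = 8000.0


@dataclass
class Lesion:
    """One plaque lesion: a (θ, z) span with a tissue class and geometry.

    θ spans may wrap through θ = 0.  ``ambiguous`` renders a calcium lesion
    with lipid-like diffuse attenuation (see module docstring).
    """

    tissue: str  # "lipid" or "calcium"
    theta_start: int
    theta_extent: int
    z_start: int
    z_extent: int
    cap_thickness_px: int = 30
    thickness_px: int = 110
    ambiguous: bool = False

    def theta_indices(self, n_theta: int) -> np.ndarray:
        return (self.theta_start + np.arange(self.theta_extent)) % n_theta

    def covers_frame(self, z: int) -> bool:
        return self.z_start <= z < self.z_start + self.z_extent


@dataclass
class PhantomConfig:
    """Full description of one synthetic VOI (pullback phantom)."""

    n_frames: int = 40
    n_r: int = 968
    n_theta: int = 496
    lumen_radius_px: float = 230.0
    eccentricity_amplitude: float = 0.08
    flatten_at_calcium: bool = True
    guidewire_center_theta: int = 60
    guidewire_width: int = 24
    lesions: list[Lesion] = field(default_factory=list)
    appearance: TissueAppearance = field(default_factory=TissueAppearance)
    wall_depth_px: int = 260
    sheath_radius_px: int = 10
    sheath_width_px: int = 4
    speckle_shape: float = 4.0  # gamma shape; 0 disables speckle
    radial_pitch_mm: float = 0.005
    pullback_speed_mm_s: float = 36.0
    frame_rate_fps: float = 180.0
    voi_id: str = "phantom-0"
    seed: int = 0

    def validate(self) -> None:
        for les in self.lesions:
            if les.tissue not in ("lipid", "calcium"):
                raise ValueError(f"unknown lesion tissue {les.tissue!r}")
            if not (0 < les.theta_extent <= self.n_theta):
                raise ValueError("lesion θ extent outside grid")
            if les.z_start < 0 or les.z_start + les.z_extent > self.n_frames:
                raise ValueError("lesion z span outside pullback")
        # overlapping lipid and calcium at the same (θ, z) is ill-posed
        occupancy: dict[tuple[int, int], str] = {}
        for les in self.lesions:
            for z in range(les.z_start, les.z_start + les.z_extent):
                for t in les.theta_indices(self.n_theta):
                    key = (int(t), z)
                    prev = occupancy.get(key)
                    if prev is not None and prev != les.tissue:
                        raise ValueError(
                            f"lipid and calcium lesions overlap at θ={t}, z={z}"
                        )
                    occupancy[key] = les.tissue


def _chord_radius(boundary_r: np.ndarray, thetas: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Radius along rays ``idx`` of the chord joining the span's end points."""
    t0, t1 = idx[0], idx[-1]
    p0 = boundary_r[t0] * np.array([np.cos(thetas[t0]), np.sin(thetas[t0])])
    p1 = boundary_r[t1] * np.array([np.cos(thetas[t1]), np.sin(thetas[t1])])
    d = p1 - p0
    u = np.stack([np.cos(thetas[idx]), np.sin(thetas[idx])], axis=-1)
    denom = u[:, 0] * d[1] - u[:, 1] * d[0]
    num = p0[0] * d[1] - p0[1] * d[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / denom
    r = np.where(np.isfinite(r) & (r > 0), r, boundary_r[idx])
    return np.minimum(r, boundary_r[idx])


def _frame_contour(cfg: PhantomConfig, z: int) -> np.ndarray:
    thetas = 2 * np.pi * np.arange(cfg.n_theta) / cfg.n_theta
    phase = 0.7 + 0.05 * z
    radius = cfg.lumen_radius_px * (1.0 + 0.02 * np.sin(2 * np.pi * z / max(cfg.n_frames, 1)))
    boundary = radius * (1.0 + cfg.eccentricity_amplitude * np.cos(thetas - phase))
    if cfg.flatten_at_calcium:
        for les in cfg.lesions:
            if les.tissue == "calcium" and les.covers_frame(z):
                idx = les.theta_indices(cfg.n_theta)
                boundary[idx] = _chord_radius(boundary, thetas, idx)
    return boundary


def _render_frame(
    cfg: PhantomConfig, z: int, boundary: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render one noise-free (r, θ) frame and its pixel annotation mask."""
    app = cfg.appearance
    r = np.arange(cfg.n_r)[:, None]
    depth = r - boundary[None, :]  # px beyond the lumen boundary

    frame = np.full((cfg.n_r, cfg.n_theta), app.lumen_floor)
    mask = np.full((cfg.n_r, cfg.n_theta), int(PixelLabel.LUMEN), dtype=np.uint8)

    in_wall = (depth >= 0) & (depth < cfg.wall_depth_px)
    fibrous = app.fibrous_intensity * np.exp(-app.fibrous_attenuation * np.maximum(depth, 0))
    frame = np.where(depth >= 0, np.maximum(fibrous, app.lumen_floor), frame)
    mask[in_wall] = int(PixelLabel.OTHER_TISSUE)
    mask[depth >= cfg.wall_depth_px] = int(PixelLabel.BACKGROUND)

    for les in cfg.lesions:
        if not les.covers_frame(z):
            continue
        cols = les.theta_indices(cfg.n_theta)
        d = depth[:, cols]
        in_lesion = (d >= les.cap_thickness_px) & (d < les.cap_thickness_px + les.thickness_px)
        dl = np.maximum(d - les.cap_thickness_px, 0)
        sub = frame[:, cols]
        msub = mask[:, cols]
        if les.tissue == "lipid":
            profile = app.lipid_intensity * np.exp(-app.lipid_attenuation * dl)
            sub = np.where(d >= les.cap_thickness_px, np.maximum(profile, app.lumen_floor), sub)
            msub = np.where(in_lesion, int(PixelLabel.LIPID), msub)
        elif les.ambiguous:
            # diffuse calcium: lipid-like attenuation profile, soft borders
            profile = app.ambiguous_intensity * np.exp(-app.ambiguous_attenuation * dl)
            sub = np.where(d >= les.cap_thickness_px, np.maximum(profile, app.lumen_floor), sub)
            msub = np.where(in_lesion, int(PixelLabel.CALCIUM), msub)
        else:
            interior = (
                app.fibrous_intensity
                * app.calcium_intensity_factor
                * np.exp(-app.calcium_attenuation * dl)
            )
            behind = (
                app.fibrous_intensity
                * app.behind_calcium_factor
                * np.exp(-app.fibrous_attenuation * np.maximum(d, 0))
            )
            sub = np.where(in_lesion, interior, sub)
            sub = np.where(
                d >= les.cap_thickness_px + les.thickness_px,
                np.maximum(behind, app.lumen_floor),
                sub,
            )
            msub = np.where(in_lesion, int(PixelLabel.CALCIUM), msub)
        frame[:, cols] = sub
        mask[:, cols] = msub

    # catheter sheath: bright ring the lumen DP must learn to skip
    ring = slice(cfg.sheath_radius_px, cfg.sheath_radius_px + cfg.sheath_width_px)
    frame[ring, :] = app.sheath_intensity

    # guidewire shadow sector
    if cfg.guidewire_width > 0:
        gw = (cfg.guidewire_center_theta - cfg.guidewire_width // 2 + np.arange(cfg.guidewire_width)) % cfg.n_theta
        frame[:, gw] = app.shadow_floor
        frame[ring, gw] = app.sheath_reflection_in_shadow

    if cfg.speckle_shape > 0:
        speckle = rng.gamma(cfg.speckle_shape, 1.0 / cfg.speckle_shape, size=frame.shape)
        frame = frame * speckle
    return np.clip(frame, 0, 65535), mask


def guidewire_indices(cfg: PhantomConfig) -> np.ndarray:
    """θ indices of the configured guidewire sector (empty if width 0)."""
    if cfg.guidewire_width <= 0:
        return np.array([], dtype=int)
    start = cfg.guidewire_center_theta - cfg.guidewire_width // 2
    return (start + np.arange(cfg.guidewire_width)) % cfg.n_theta


def generate_pullback(
    cfg: PhantomConfig,
) -> tuple[PolarPullback, np.ndarray, list[LumenContour], np.ndarray]:
    """Generate one phantom pullback.

    Returns
    -------
    pullback:
        :class:`PolarPullback` with speckled frames.
    masks:
        ``(n_frames, n_r, n_theta)`` pixel annotation stack.
    contours:
        ground-truth lumen contour per frame (guidewire A-lines flagged).
    labels:
        ``(n_theta, n_frames)`` ground-truth A-line label grid, derived from
        the pixel masks via the ≥3-pixel majority rule, with the guidewire
        sector overridden to ``GUIDEWIRE``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    frames = np.empty((cfg.n_frames, cfg.n_r, cfg.n_theta))
    masks = np.empty((cfg.n_frames, cfg.n_r, cfg.n_theta), dtype=np.uint8)
    contours: list[LumenContour] = []
    labels = np.empty((cfg.n_theta, cfg.n_frames), dtype=np.int8)
    gw = guidewire_indices(cfg)
    for z in range(cfg.n_frames):
        boundary = _frame_contour(cfg, z)
        frame, mask = _render_frame(cfg, z, boundary, rng)
        frames[z] = frame
        masks[z] = mask
        valid = np.ones(cfg.n_theta, dtype=bool)
        valid[gw] = False
        contours.append(LumenContour(boundary_r=boundary, valid_mask=valid))
        lab = pixel_mask_to_aline_labels(mask)
        lab[gw] = int(ALineLabel.GUIDEWIRE)
        labels[:, z] = lab
    pullback = PolarPullback(
        frames,
        radial_pitch_mm=cfg.radial_pitch_mm,
        pullback_speed_mm_s=cfg.pullback_speed_mm_s,
        frame_rate_fps=cfg.frame_rate_fps,
        voi_id=cfg.voi_id,
    )
    return pullback, masks, contours, labels


# ---------------------------------------------------------------------------
# dataset-level generation


@dataclass
class SyntheticVoi:
    """One generated VOI with its full ground truth."""

    config: PhantomConfig
    pullback: PolarPullback
    masks: np.ndarray
    contours: list[LumenContour]
    labels: np.ndarray
    kind: str  # "calcium" | "lipid" | "both" | "none"


@dataclass
class SyntheticDataset:
    vois: list[SyntheticVoi]
    folds: FoldSplit

    def voi(self, voi_id: str) -> SyntheticVoi:
        for v in self.vois:
            if v.config.voi_id == voi_id:
                return v
        raise KeyError(voi_id)


def default_voi_mix(n_vois: int) -> list[str]:
    """VOI lesion-composition mix, largest-remainder scaled from 34:37:13:27.

    The reference composition is 34 calcium-only, 37 lipid-only, 13 with both,
    and 27 without lesions, out of 111.
    """
    ref = {"calcium": 34, "lipid": 37, "both": 13, "none": 27}
    total = sum(ref.values())
    quotas = {k: n_vois * v / total for k, v in ref.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n_vois - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in by_remainder[:short]:
        counts[k] += 1
    kinds: list[str] = []
    for k in ("calcium", "lipid", "both", "none"):
        kinds.extend([k] * counts[k])
    return kinds


#: Fraction of calcium lesions rendered with ambiguous (lipid-like) appearance.
AMBIGUOUS_CALCIUM_FRACTION = 0.35


def sample_voi_config(
    kind: str, rng: np.random.Generator, base: PhantomConfig | None = None, voi_id: str = "voi"
) -> PhantomConfig:
    """Draw one VOI's phantom configuration for the given lesion composition."""
    base = base or PhantomConfig()
    cfg = replace(
        base,
        lesions=[],
        voi_id=voi_id,
        seed=int(rng.integers(0, 2**31 - 1)),
        lumen_radius_px=base.lumen_radius_px * float(rng.uniform(0.85, 1.1)),
        eccentricity_amplitude=float(rng.uniform(0.03, 0.13)),
        guidewire_center_theta=int(rng.integers(0, base.n_theta)),
    )
    wanted = {"calcium": ["calcium"], "lipid": ["lipid"], "both": ["calcium", "lipid"], "none": []}[kind]
    lesions: list[Lesion] = []
    gw = set(guidewire_indices(cfg).tolist())
    for tissue in wanted:
        for _ in range(int(rng.integers(1, 3))):
            extent = int(rng.integers(cfg.n_theta // 8, cfg.n_theta // 3))
            z_extent = int(rng.integers(max(cfg.n_frames // 4, 2), max(3 * cfg.n_frames // 4, 3)))
            z_start = int(rng.integers(0, cfg.n_frames - z_extent + 1))
            for _try in range(20):
                start = int(rng.integers(0, cfg.n_theta))
                cand = Lesion(
                    tissue=tissue,
                    theta_start=start,
                    theta_extent=extent,
                    z_start=z_start,
                    z_extent=z_extent,
                    cap_thickness_px=int(rng.integers(20, 45)),
                    thickness_px=int(rng.integers(70, 140)),
                    ambiguous=(
                        tissue == "calcium"
                        and rng.random() < AMBIGUOUS_CALCIUM_FRACTION
                    ),
                )
                span = set(cand.theta_indices(cfg.n_theta).tolist())
                clash = any(
                    l.tissue != tissue
                    and not (
                        z_start + z_extent <= l.z_start or l.z_start + l.z_extent <= z_start
                    )
                    and span & set(l.theta_indices(cfg.n_theta).tolist())
                    for l in lesions
                )
                if not clash:
                    lesions.append(cand)
                    break
    cfg.lesions = lesions
    return cfg


def generate_dataset(
    n_vois: int,
    seed: int,
    base: PhantomConfig | None = None,
    n_folds: int = 5,
    held_out_fraction: float = 0.0,
    sampler=sample_voi_config,
) -> SyntheticDataset:
    """Generate ``n_vois`` phantoms plus a VOI-granularity fold split."""
    from .evaluation import make_folds

    if n_vois < n_folds:
        raise ValueError(f"need at least {n_folds} VOIs, got {n_vois}")
    rng = np.random.default_rng(seed)
    kinds = default_voi_mix(n_vois)
    rng.shuffle(kinds)
    vois = []
    for i, kind in enumerate(kinds):
        cfg = sampler(kind, rng, base=base, voi_id=f"voi-{i:03d}")
        pullback, masks, contours, labels = generate_pullback(cfg)
        vois.append(
            SyntheticVoi(
                config=cfg,
                pullback=pullback,
                masks=masks,
                contours=contours,
                labels=labels,
                kind=kind,
            )
        )
    folds = make_folds(
        [v.config.voi_id for v in vois],
        n_folds=n_folds,
        held_out_fraction=held_out_fraction,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return SyntheticDataset(vois=vois, folds=folds)
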