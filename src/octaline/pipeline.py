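"""End-to-end orchestration: simulate, train, predict, evaluate.

The processing chain per pullback is: pre-process (guidewire detection,
lumen segmentation, pixel shift, ROI crop + denoise) → CNN feature
extraction per A-line → lumen morphology features per A-line → hybrid
random-forest classification → dense-CRF smoothing of the en-face map.

Disk layout for a simulated dataset::

    dataset/
      manifest.json            # seeds, scale, VOI ids
      folds.yaml               # VOI-level fold assignments
      voi-000/
        pullback.tiff(+.json)  # polar frames + calibration sidecar
        masks.tiff             # pixel annotations
        contours.csv           # ground-truth lumen contours
        labels.csv             # ground-truth A-line label grid (θ rows)

A trained fold bundle holds the fitted CNN, forest, CRF parameters and a
JSON manifest tying every artifact to its seeds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import joblib
import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from .cnn import ALineCNN
from .crf import CrfParams, EnFaceCRF
from .data import ALineLabel, EnFaceMap, FoldSplit, LumenContour, PolarPullback
from .hybrid import HybridForestClassifier, assemble_hybrid_features
from .io import ENFACE_PALETTE, read_contours, read_mask_stack, read_pullback
from .io import write_contours, write_enface, write_mask_stack, write_pullback
from .morphology import MorphologyFeatureExtractor
from .phantom import PhantomConfig, SyntheticDataset, SyntheticVoi, generate_dataset
from .preprocess import preprocess_pullback

__all__ = [
    "VoiFeatures",
    "compute_voi_features",
    "stratified_subsample",
    "FoldBundle",
    "train_fold",
    "predict_enface",
    "run_simulate",
    "run_train",
    "run_predict",
    "run_evaluate",
    "scan_convert",
    "render_ring_overlay",
]


# ---------------------------------------------------------------------------
# feature computation


@dataclass
class VoiFeatures:
    """Cached per-VOI inputs to classification.

    Rows are A-lines in frame-major order (frame 0 θ 0..n−1, frame 1, ...).
    """

    voi_id: str
    alines: np.ndarray  # (n_alines, 205) processed ROI + pad source
    morph: np.ndarray  # (n_alines, n_morph)
    labels: np.ndarray  # (n_alines,) ground-truth ALineLabel codes
    n_theta: int
    n_frames: int
    frame_interval_mm: float
    morph_names: list | None = None

    @property
    def tissue_rows(self) -> np.ndarray:
        return self.labels != int(ALineLabel.GUIDEWIRE)

    def label_grid(self) -> np.ndarray:
        """(n_theta, n_frames) reference label grid."""
        return self.labels.reshape(self.n_frames, self.n_theta).T


def compute_voi_features(
    pullback: PolarPullback,
    label_grid: np.ndarray,
    morph_extractor: MorphologyFeatureExtractor | None = None,
    use_contours: list[LumenContour] | None = None,
) -> VoiFeatures:
    """Run pre-processing + morphology on one pullback.

    ``label_grid`` is the (n_theta, n_frames) reference grid (phantom ground
    truth or annotation-derived labels); ``use_contours`` bypasses lumen
    segmentation with known contours.
    """
    morph_extractor = morph_extractor or MorphologyFeatureExtractor()
    processed, contours, _ = preprocess_pullback(pullback, use_contours=use_contours)
    alines = np.concatenate([p.data.T for p in processed], axis=0)
    morph = morph_extractor.transform_pullback(contours)
    labels = np.asarray(label_grid).T.reshape(-1).astype(int)
    if labels.size != alines.shape[0]:
        raise ValueError("label grid does not match pullback shape")
    return VoiFeatures(
        voi_id=pullback.voi_id,
        alines=alines,
        morph=morph,
        labels=labels,
        n_theta=pullback.n_theta,
        n_frames=pullback.n_frames,
        frame_interval_mm=pullback.frame_interval_mm,
        morph_names=morph_extractor.feature_names,
    )


def stratified_subsample(
    y: np.ndarray, max_rows: int, rng: np.random.Generator
) -> np.ndarray:
    """Row indices of a class-proportional subsample of at most ``max_rows``.

    Every present class keeps at least one row; tiny classes are kept whole.
    """
    y = np.asarray(y)
    n = y.size
    if n <= max_rows:
        return np.arange(n)
    keep: list[np.ndarray] = []
    for cls in np.unique(y):
        rows = np.flatnonzero(y == cls)
        quota = max(int(round(max_rows * rows.size / n)), 1)
        if rows.size <= quota:
            keep.append(rows)
        else:
            keep.append(rng.choice(rows, size=quota, replace=False))
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# fold training


@dataclass
class FoldBundle:
    """Everything fitted for one cross-validation fold."""

    cnn: ALineCNN
    forest: HybridForestClassifier
    crf_params: CrfParams
    morph_extractor: MorphologyFeatureExtractor
    manifest: dict

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.cnn, out_dir / "cnn.joblib")
        joblib.dump(self.forest, out_dir / "forest.joblib")
        (out_dir / "crf.json").write_text(json.dumps(asdict(self.crf_params), indent=1))
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        joblib.dump(self.morph_extractor, out_dir / "morphology.joblib")
        return out_dir

    @classmethod
    def load(cls, out_dir: str | Path) -> "FoldBundle":
        out_dir = Path(out_dir)
        return cls(
            cnn=joblib.load(out_dir / "cnn.joblib"),
            forest=joblib.load(out_dir / "forest.joblib"),
            crf_params=CrfParams(**json.loads((out_dir / "crf.json").read_text())),
            morph_extractor=joblib.load(out_dir / "morphology.joblib"),
            manifest=json.loads((out_dir / "manifest.json").read_text()),
        )


def _gather(features: list[VoiFeatures], tissue_only: bool = True):
    alines = np.concatenate([f.alines for f in features])
    morph = np.concatenate([f.morph for f in features])
    labels = np.concatenate([f.labels for f in features])
    if tissue_only:
        keep = labels != int(ALineLabel.GUIDEWIRE)
        return alines[keep], morph[keep], labels[keep]
    return alines, morph, labels


def train_fold(
    train_features: list[VoiFeatures],
    val_features: list[VoiFeatures],
    seed: int = 0,
    max_cnn_rows: int = 9000,
    max_rf_rows: int = 8000,
    cnn_params: dict | None = None,
    rf_params: dict | None = None,
    crf_grid: list[CrfParams] | None = None,
) -> FoldBundle:
    """Fit CNN → hybrid forest → CRF parameters for one fold.

    Guidewire A-lines never enter training.  A-line rows are subsampled
    (class-proportional) to the given caps to keep CPU training fast; the
    manifest records the realized sizes.
    """
    rng = np.random.default_rng(seed)
    xa_tr, xm_tr, y_tr = _gather(train_features)
    xa_va, xm_va, y_va = _gather(val_features)

    tr_idx = stratified_subsample(y_tr, max_cnn_rows, rng)
    va_idx = stratified_subsample(y_va, max(max_cnn_rows // 3, 500), rng)
    cnn = ALineCNN(random_state=seed, **(cnn_params or {}))
    cnn.fit(
        xa_tr[tr_idx], y_tr[tr_idx], validation_data=(xa_va[va_idx], y_va[va_idx])
    )

    rf_idx = stratified_subsample(y_tr, max_rf_rows, rng)
    cnn_feat = cnn.transform(xa_tr[rf_idx])
    hybrid = assemble_hybrid_features(cnn_feat, xm_tr[rf_idx])
    feature_names = None
    if train_features[0].morph_names is not None:
        feature_names = [f"cnn_{i}" for i in range(cnn_feat.shape[1])] + [
            f"morph_{n}" for n in train_features[0].morph_names
        ]
    forest = HybridForestClassifier(random_state=seed, **(rf_params or {}))
    forest.fit(hybrid, y_tr[rf_idx], feature_names=feature_names)

    # CRF parameters from validation maps
    crf = EnFaceCRF(grid=crf_grid)
    val_maps = []
    for f in val_features:
        enface = predict_enface(cnn, forest, f, crf_params=None)
        val_maps.append((enface, f.label_grid()))
    crf.fit(val_maps)

    manifest = {
        "seed": seed,
        "n_train_vois": len(train_features),
        "n_val_vois": len(val_features),
        "cnn_rows": int(tr_idx.size),
        "rf_rows": int(rf_idx.size),
        "cnn": cnn.manifest(),
        "rf": {"n_trees": forest.n_trees_, "oob_score": forest.oob_score_},
        "crf": asdict(crf.params_),
        "crf_grid_scores": [float(s) for s in crf.grid_scores_],
        "stages": ["preprocess", "cnn_features", "morph_features", "random_forest", "crf"],
    }
    return FoldBundle(
        cnn=cnn,
        forest=forest,
        crf_params=crf.params_,
        morph_extractor=MorphologyFeatureExtractor(),
        manifest=manifest,
    )


def predict_enface(
    cnn: ALineCNN,
    forest: HybridForestClassifier,
    features: VoiFeatures,
    crf_params: CrfParams | None = None,
) -> EnFaceMap:
    """Classify every A-line of a VOI and assemble the en-face map.

    Guidewire cells (from the reference grid) are masked.  With
    ``crf_params`` the map is additionally mean-field smoothed.
    """
    from .crf import mean_field_infer

    cnn_feat = cnn.transform(features.alines)
    hybrid = assemble_hybrid_features(cnn_feat, features.morph)
    raw = forest.predict_proba(hybrid)
    probs = _expand_probs(raw, forest.classes_)
    grid = probs.reshape(features.n_frames, features.n_theta, 3).transpose(1, 0, 2)
    labels = np.argmax(grid, axis=-1).astype(np.int8)
    gw = features.label_grid() == int(ALineLabel.GUIDEWIRE)
    labels[gw] = int(ALineLabel.GUIDEWIRE)
    enface = EnFaceMap(labels=labels, probs=grid)
    if crf_params is not None:
        enface = mean_field_infer(enface, crf_params)
    return enface


def _expand_probs(probs: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Expand forest probabilities to the full 3-class layout."""
    out = np.zeros((probs.shape[0], 3))
    for j, cls in enumerate(classes):
        out[:, int(cls)] = probs[:, j]
    return out


# ---------------------------------------------------------------------------
# disk-level commands (CLI surface)


def run_simulate(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Generate a synthetic dataset on disk from a YAML/dict config."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.get("seed")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31 - 1))
    base_kwargs = config.get("phantom", {})
    base = PhantomConfig(**base_kwargs) if base_kwargs else None
    dataset = generate_dataset(
        n_vois=int(config.get("n_vois", 10)),
        seed=int(seed),
        base=base,
        n_folds=int(config.get("n_folds", 5)),
        held_out_fraction=float(config.get("held_out_fraction", 0.0)),
    )
    for voi in dataset.vois:
        voi_dir = out_dir / voi.config.voi_id
        write_pullback(voi.pullback, voi_dir / "pullback.tiff")
        write_mask_stack(voi.masks, voi_dir / "masks.tiff")
        write_contours(voi.contours, voi_dir / "contours.csv")
        np.savetxt(voi_dir / "labels.csv", voi.labels, fmt="%d", delimiter=",")
    (out_dir / "folds.yaml").write_text(
        yaml.safe_dump({"folds": dataset.folds.folds, "held_out": dataset.folds.held_out})
    )
    manifest = {
        "seed": int(seed),
        "n_vois": len(dataset.vois),
        "voi_ids": [v.config.voi_id for v in dataset.vois],
        "kinds": {v.config.voi_id: v.kind for v in dataset.vois},
        "phantom": base_kwargs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir


def load_dataset_dir(dataset_dir: str | Path) -> SyntheticDataset:
    """Load a simulated dataset directory back into memory."""
    dataset_dir = Path(dataset_dir)
    manifest = json.loads((dataset_dir / "manifest.json").read_text())
    folds_raw = yaml.safe_load((dataset_dir / "folds.yaml").read_text())
    vois = []
    for voi_id in manifest["voi_ids"]:
        voi_dir = dataset_dir / voi_id
        pullback = read_pullback(voi_dir / "pullback.tiff")
        masks = read_mask_stack(voi_dir / "masks.tiff")
        contours = read_contours(voi_dir / "contours.csv")
        labels = np.loadtxt(voi_dir / "labels.csv", dtype=int, delimiter=",", ndmin=2)
        cfg = PhantomConfig(
            n_frames=pullback.n_frames,
            n_r=pullback.n_r,
            n_theta=pullback.n_theta,
            voi_id=voi_id,
        )
        vois.append(
            SyntheticVoi(
                config=cfg,
                pullback=pullback,
                masks=masks,
                contours=contours,
                labels=labels.astype(np.int8),
                kind=manifest.get("kinds", {}).get(voi_id, "unknown"),
            )
        )
    folds = FoldSplit(folds=folds_raw["folds"], held_out=folds_raw.get("held_out", []))
    return SyntheticDataset(vois=vois, folds=folds)


def run_train(
    dataset_dir: str | Path,
    out_dir: str | Path,
    fold: int = 0,
    seed: int = 0,
    use_ground_truth_contours: bool = False,
    **train_kwargs,
) -> Path:
    """Train one fold's model bundle from a dataset directory."""
    dataset = load_dataset_dir(dataset_dir)
    fold_spec = dataset.folds.folds[fold]
    feats = {}
    for role in ("train", "validation"):
        feats[role] = []
        for voi_id in fold_spec[role]:
            voi = dataset.voi(voi_id)
            feats[role].append(
                compute_voi_features(
                    voi.pullback,
                    voi.labels,
                    use_contours=voi.contours if use_ground_truth_contours else None,
                )
            )
    bundle = train_fold(feats["train"], feats["validation"], seed=seed, **train_kwargs)
    bundle.manifest["dataset_dir"] = str(dataset_dir)
    bundle.manifest["fold"] = fold
    return bundle.save(Path(out_dir) / f"fold-{fold}")


def run_predict(
    pullback_path: str | Path,
    bundle_dir: str | Path,
    out_dir: str | Path,
    reference_labels: str | Path | None = None,
    overlays: bool = False,
) -> Path:
    """Full-pipeline inference on one pullback; writes en-face CSV/PNG."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = FoldBundle.load(bundle_dir)
    pullback = read_pullback(pullback_path)
    if reference_labels is not None:
        ref = np.loadtxt(reference_labels, dtype=int, delimiter=",", ndmin=2)
    else:
        ref = np.full((pullback.n_theta, pullback.n_frames), int(ALineLabel.OTHER))
    features = compute_voi_features(pullback, ref, morph_extractor=bundle.morph_extractor)
    pre = predict_enface(bundle.cnn, bundle.forest, features)
    post = predict_enface(bundle.cnn, bundle.forest, features, crf_params=bundle.crf_params)
    write_enface(pre, out_dir / "enface_raw")
    write_enface(post, out_dir / "enface_smoothed")
    if overlays:
        overlay_dir = out_dir / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        for z in range(pullback.n_frames):
            img = render_ring_overlay(
                pullback.frames[z],
                predicted=post.labels[:, z],
                reference=ref[:, z] if reference_labels is not None else None,
            )
            Image.fromarray(img).save(overlay_dir / f"frame-{z:04d}.png")
    return out_dir


def run_evaluate(
    predictions: EnFaceMap | np.ndarray,
    references: np.ndarray | None,
    frame_interval_mm: float = 0.2,
) -> dict:
    """Metrics + plaque attributes for one prediction/reference pair.

    Without a reference, only attributes of the prediction are reported.
    """
    from .evaluation import arc_angle, confusion_metrics, plaque_length

    pred = predictions.labels if isinstance(predictions, EnFaceMap) else np.asarray(predictions)
    out: dict = {"attributes": {}}
    for label in (ALineLabel.FIBROLIPIDIC, ALineLabel.FIBROCALCIFIC):
        arcs = [a for z in range(pred.shape[1]) for a in arc_angle(pred[:, z], label)]
        lengths = [
            l for per_theta in plaque_length(pred, label, frame_interval_mm) for l in per_theta
        ]
        out["attributes"][label.name] = {
            "arc_angles_deg": arcs,
            "lengths_mm": lengths,
        }
    if references is not None:
        report = confusion_metrics(pred, np.asarray(references))
        out["metrics"] = report.per_class
        out["mean_f1"] = report.mean_f1()
    return out


# ---------------------------------------------------------------------------
# display helpers (polar → Cartesian for overlays only)


def scan_convert(frame: np.ndarray, size: int = 512, log_display: bool = True) -> np.ndarray:
    """Bilinear polar → Cartesian conversion for display.

    All computation in this package stays polar; this exists only to render
    overlays.  Intensities are log-transformed for display by default.
    """
    n_r, n_theta = frame.shape
    ys, xs = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    dx, dy = xs - cx, ys - cy
    radius = np.sqrt(dx * dx + dy * dy) * (n_r / (size / 2.0))
    angle = np.mod(np.arctan2(dy, dx), 2 * np.pi) * n_theta / (2 * np.pi)
    data = np.log1p(np.asarray(frame, dtype=float)) if log_display else np.asarray(frame, float)
    out = ndimage.map_coordinates(data, [radius, angle], order=1, mode="grid-wrap", cval=0.0)
    out[radius >= n_r] = 0.0
    return out


def render_ring_overlay(
    frame: np.ndarray,
    predicted: np.ndarray,
    reference: np.ndarray | None = None,
    size: int = 512,
) -> np.ndarray:
    """Scan-converted frame with label rings: inner = reference, outer = predicted."""
    base = scan_convert(frame, size=size)
    lo, hi = base.min(), base.max()
    gray = ((base - lo) / (hi - lo + 1e-12) * 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    n_theta = predicted.size
    ys, xs = np.mgrid[0:size, 0:size]
    cx = cy = (size - 1) / 2.0
    radius = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
    angle_idx = (np.mod(np.arctan2(ys - cy, xs - cx), 2 * np.pi) * n_theta / (2 * np.pi)).astype(int) % n_theta
    rings = [(predicted, 0.94, 1.0)]
    if reference is not None:
        rings.append((reference, 0.87, 0.93))
    for labels, r0, r1 in rings:
        band = (radius >= r0 * size / 2) & (radius < r1 * size / 2)
        colors = np.array([ENFACE_PALETTE[int(c)] for c in labels], dtype=np.uint8)
        rgb[band] = colors[angle_idx[band]]
    return rgb
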