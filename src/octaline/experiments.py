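"""Scaled-down end-to-end cross-validation experiment on synthetic pullbacks.

Runs the full pipeline — phantom generation, pre-processing with the
package's own lumen segmentation, CNN + morphology feature extraction,
hybrid random-forest classification, CRF smoothing — under five-fold
VOI-level cross validation, and compares three classifiers per fold:

* hybrid: random forest on convolutional + morphology features;
* CNN-only: the CNN's own softmax classification;
* morphology-only: random forest on morphology features alone.

The default problem size (25 VOIs × 40 frames, 96 A-lines of 360 radial
samples each) is chosen so the whole study runs in minutes on one CPU while
keeping every stage of the method intact; the VOI composition follows the
34:37:13:27 calcium/lipid/both/none reference mix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn import ALineCNN
from .crf import CrfParams, EnFaceCRF
from .data import ALineLabel
from .evaluation import (
    arc_angle,
    bland_altman,
    confusion_metrics,
    paired_wilcoxon,
    plaque_length,
)
from .hybrid import HybridForestClassifier, assemble_hybrid_features
from .phantom import PhantomConfig, generate_dataset
from .pipeline import (
    VoiFeatures,
    _expand_probs,
    compute_voi_features,
    predict_enface,
    stratified_subsample,
    train_fold,
)

__all__ = ["ExperimentConfig", "ExperimentResult", "run_crossval_experiment"]


@dataclass
class ExperimentConfig:
    """Problem sizes and training caps for the cross-validation study."""

    n_vois: int = 25
    n_frames: int = 40
    n_theta: int = 96
    n_r: int = 360
    lumen_radius_px: float = 100.0
    guidewire_width: int = 6
    n_folds: int = 5
    seed: int = 0
    max_cnn_rows: int = 9000
    max_rf_rows: int = 8000
    cnn_max_epochs: int = 15
    rf_trees: int = 250
    crf_grid: list = field(
        default_factory=lambda: [CrfParams(omega1=0.0)]
        + [CrfParams(omega1=w, theta_alpha=a) for w in (1.0, 2.0) for a in (1.5, 3.0)]
    )

    def base_phantom(self) -> PhantomConfig:
        return PhantomConfig(
            n_frames=self.n_frames,
            n_r=self.n_r,
            n_theta=self.n_theta,
            lumen_radius_px=self.lumen_radius_px,
            guidewire_width=self.guidewire_width,
            wall_depth_px=min(230, self.n_r - 130),
        )


@dataclass
class FoldResult:
    fold: int
    f1_pre_crf: dict[str, float | None]
    f1_post_crf: dict[str, float | None]
    mean_f1_hybrid: float
    mean_f1_hybrid_pre: float
    mean_f1_cnn_only: float
    mean_f1_morph_only: float


@dataclass
class ExperimentResult:
    folds: list[FoldResult]
    arc_angle_agreement: dict[str, dict]
    length_agreement: dict[str, dict]
    wilcoxon_pre_vs_post_p: float

    def per_class_f1_post(self) -> dict[str, float]:
        """Mean over folds of the per-class post-CRF F1 (defined entries)."""
        out = {}
        for cls in ("FIBROLIPIDIC", "FIBROCALCIFIC", "OTHER"):
            vals = [f.f1_post_crf[cls] for f in self.folds if f.f1_post_crf[cls] is not None]
            out[cls] = float(np.mean(vals)) if vals else float("nan")
        return out

    def hybrid_wins(self) -> tuple[int, int]:
        """Folds where hybrid mean F1 strictly beats (CNN-only, morph-only)."""
        cnn = sum(f.mean_f1_hybrid > f.mean_f1_cnn_only for f in self.folds)
        morph = sum(f.mean_f1_hybrid > f.mean_f1_morph_only for f in self.folds)
        return cnn, morph


def _collect(features: list[VoiFeatures]):
    alines = np.concatenate([f.alines for f in features])
    morph = np.concatenate([f.morph for f in features])
    labels = np.concatenate([f.labels for f in features])
    keep = labels != int(ALineLabel.GUIDEWIRE)
    return alines[keep], morph[keep], labels[keep]


def _enface_from_probs(features: VoiFeatures, probs: np.ndarray):
    from .data import EnFaceMap

    grid = probs.reshape(features.n_frames, features.n_theta, 3).transpose(1, 0, 2)
    labels = np.argmax(grid, axis=-1).astype(np.int8)
    gw = features.label_grid() == int(ALineLabel.GUIDEWIRE)
    labels[gw] = int(ALineLabel.GUIDEWIRE)
    return EnFaceMap(labels=labels, probs=grid)


def run_crossval_experiment(
    cfg: ExperimentConfig | None = None, verbose: bool = False
) -> ExperimentResult:
    """Run the full cross-validation study; see module docstring."""
    cfg = cfg or ExperimentConfig()
    dataset = generate_dataset(
        n_vois=cfg.n_vois,
        seed=cfg.seed,
        base=cfg.base_phantom(),
        n_folds=cfg.n_folds,
    )
    features: dict[str, VoiFeatures] = {}
    for voi in dataset.vois:
        features[voi.config.voi_id] = compute_voi_features(voi.pullback, voi.labels)

    fold_results: list[FoldResult] = []
    pred_arcs: dict[str, list[float]] = {"FIBROLIPIDIC": [], "FIBROCALCIFIC": []}
    ref_arcs: dict[str, list[float]] = {"FIBROLIPIDIC": [], "FIBROCALCIFIC": []}
    pred_lens: dict[str, list[float]] = {"FIBROLIPIDIC": [], "FIBROCALCIFIC": []}
    ref_lens: dict[str, list[float]] = {"FIBROLIPIDIC": [], "FIBROCALCIFIC": []}

    for i, fold in enumerate(dataset.folds.folds):
        train_feats = [features[v] for v in fold["train"]]
        val_feats = [features[v] for v in fold["validation"]]
        test_feats = [features[v] for v in fold["test"]]
        fold_seed = cfg.seed * 1000 + i

        bundle = train_fold(
            train_feats,
            val_feats,
            seed=fold_seed,
            max_cnn_rows=cfg.max_cnn_rows,
            max_rf_rows=cfg.max_rf_rows,
            cnn_params={"max_epochs": cfg.cnn_max_epochs},
            rf_params={"n_trees": cfg.rf_trees},
            crf_grid=cfg.crf_grid,
        )

        # morphology-only baseline, trained identically
        rng = np.random.default_rng(fold_seed + 7)
        xa_tr, xm_tr, y_tr = _collect(train_feats)
        rf_idx = stratified_subsample(y_tr, cfg.max_rf_rows, rng)
        morph_only = HybridForestClassifier(n_trees=cfg.rf_trees, random_state=fold_seed)
        morph_only.fit(xm_tr[rf_idx], y_tr[rf_idx])

        pre_all, post_all, ref_all = [], [], []
        cnn_pred_all, morph_pred_all = [], []
        for f in test_feats:
            pre = predict_enface(bundle.cnn, bundle.forest, f)
            post = predict_enface(bundle.cnn, bundle.forest, f, crf_params=bundle.crf_params)
            ref = f.label_grid()
            pre_all.append(pre.labels)
            post_all.append(post.labels)
            ref_all.append(ref)

            cnn_probs = bundle.cnn.predict_proba(f.alines)
            cnn_map = _enface_from_probs(f, cnn_probs)
            cnn_pred_all.append(cnn_map.labels)
            morph_probs = _expand_probs(morph_only.predict_proba(f.morph), morph_only.classes_)
            morph_map = _enface_from_probs(f, morph_probs)
            morph_pred_all.append(morph_map.labels)

            # clinical attributes (per frame / per θ-line totals, post-CRF)
            for cls in (ALineLabel.FIBROLIPIDIC, ALineLabel.FIBROCALCIFIC):
                for z in range(ref.shape[1]):
                    pred_arcs[cls.name].append(sum(arc_angle(post.labels[:, z], cls)))
                    ref_arcs[cls.name].append(sum(arc_angle(ref[:, z], cls)))
                interval = f.frame_interval_mm
                for pl, rl in zip(
                    plaque_length(post.labels, cls, interval),
                    plaque_length(ref, cls, interval),
                ):
                    pred_lens[cls.name].append(sum(pl))
                    ref_lens[cls.name].append(sum(rl))

        pre_labels = np.concatenate(pre_all, axis=1)
        post_labels = np.concatenate(post_all, axis=1)
        ref_labels = np.concatenate(ref_all, axis=1)
        cnn_labels = np.concatenate(cnn_pred_all, axis=1)
        morph_labels = np.concatenate(morph_pred_all, axis=1)

        pre_report = confusion_metrics(pre_labels, ref_labels)
        post_report = confusion_metrics(post_labels, ref_labels)
        cnn_report = confusion_metrics(cnn_labels, ref_labels)
        morph_report = confusion_metrics(morph_labels, ref_labels)

        fr = FoldResult(
            fold=i,
            f1_pre_crf={k: v["f1"] for k, v in pre_report.per_class.items()},
            f1_post_crf={k: v["f1"] for k, v in post_report.per_class.items()},
            mean_f1_hybrid=post_report.mean_f1(),
            mean_f1_hybrid_pre=pre_report.mean_f1(),
            mean_f1_cnn_only=cnn_report.mean_f1(),
            mean_f1_morph_only=morph_report.mean_f1(),
        )
        fold_results.append(fr)
        if verbose:
            print(
                f"fold {i}: hybrid post-CRF mean F1 {fr.mean_f1_hybrid:.3f} "
                f"(pre {fr.mean_f1_hybrid_pre:.3f}), CNN-only {fr.mean_f1_cnn_only:.3f}, "
                f"morph-only {fr.mean_f1_morph_only:.3f}"
            )

    arc_agree, len_agree = {}, {}
    for cls in ("FIBROLIPIDIC", "FIBROCALCIFIC"):
        if len(pred_arcs[cls]) >= 2:
            ba = bland_altman(np.asarray(pred_arcs[cls]), np.asarray(ref_arcs[cls]))
            arc_agree[cls] = {k: ba[k] for k in ("bias", "sd", "lower_limit", "upper_limit")}
            ba = bland_altman(np.asarray(pred_lens[cls]), np.asarray(ref_lens[cls]))
            len_agree[cls] = {k: ba[k] for k in ("bias", "sd", "lower_limit", "upper_limit")}

    pre_vec = [f.mean_f1_hybrid_pre for f in fold_results]
    post_vec = [f.mean_f1_hybrid for f in fold_results]
    p_value = paired_wilcoxon(np.asarray(post_vec), np.asarray(pre_vec))

    return ExperimentResult(
        folds=fold_results,
        arc_angle_agreement=arc_agree,
        length_agreement=len_agree,
        wilcoxon_pre_vs_post_p=p_value,
    )
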