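"""Classification metrics, clinical plaque attributes, agreement statistics,
and cross-validation fold construction.

Per-class metrics are one-vs-rest over non-guidewire A-lines:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2·TP / (2·TP + FP + FN)

Clinical attributes: the *arc angle* of a plaque is the angular extent of a
maximal contiguous run of same-class A-lines within a frame (circular in θ,
so runs may wrap through θ = 0); the *length* is, per θ-line, the number of
contiguous frames containing the plaque multiplied by the frame interval.
Agreement between predicted and reference attributes is summarized with
Bland–Altman bias and 95% limits; paired method comparisons use the
two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import ALineLabel, FoldSplit, TISSUE_LABELS

__all__ = [
    "MetricsReport",
    "confusion_metrics",
    "arc_angle",
    "plaque_length",
    "bland_altman",
    "paired_wilcoxon",
    "make_folds",
    "select_folds_for_relabeling",
    "circular_runs",
]


@dataclass
class MetricsReport:
    """Per-class confusion counts and rates over evaluated A-lines."""

    per_class: dict[str, dict] = field(default_factory=dict)
    n_evaluated: int = 0

    def mean_f1(self) -> float:
        """Unweighted mean F1 over classes where F1 is defined."""
        f1s = [v["f1"] for v in self.per_class.values() if v["f1"] is not None]
        return float(np.mean(f1s)) if f1s else float("nan")


def confusion_metrics(pred: np.ndarray, ref: np.ndarray) -> MetricsReport:
    """One-vs-rest confusion counts and rates for the three tissue classes.

    Guidewire cells (in either grid) are excluded.  When a class has no
    positive reference A-lines its sensitivity (and F1) are reported as
    ``None`` — missing, not zero.
    """
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    keep = (pred != int(ALineLabel.GUIDEWIRE)) & (ref != int(ALineLabel.GUIDEWIRE))
    p, r = pred[keep].ravel(), ref[keep].ravel()
    report = MetricsReport(n_evaluated=int(p.size))
    for label in TISSUE_LABELS:
        code = int(label)
        tp = int(np.count_nonzero((p == code) & (r == code)))
        fp = int(np.count_nonzero((p == code) & (r != code)))
        fn = int(np.count_nonzero((p != code) & (r == code)))
        tn = int(np.count_nonzero((p != code) & (r != code)))
        sens = tp / (tp + fn) if (tp + fn) > 0 else None
        spec = tn / (tn + fp) if (tn + fp) > 0 else None
        f1 = 2 * tp / (2 * tp + fp + fn) if (tp + fn) > 0 else None
        report.per_class[label.name] = {
            "tp": tp,
            "tn": tn,
            "fp": fp,
            "fn": fn,
            "sensitivity": sens,
            "specificity": spec,
            "f1": f1,
        }
    return report


def circular_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True on a circular index domain.

    Returns (start, length) pairs; a run wrapping through index 0 is reported
    once, starting at its true beginning.
    """
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    if flags.all():
        return [(0, n)]
    if not flags.any():
        return []
    start = int(np.argmin(flags))  # begin scanning at a False
    runs: list[tuple[int, int]] = []
    run_start, count = None, 0
    for k in range(n):
        i = (start + k) % n
        if flags[i]:
            if count == 0:
                run_start = i
            count += 1
        elif count:
            runs.append((run_start, count))
            count = 0
    if count:
        runs.append((run_start, count))
    return runs


def arc_angle(frame_labels: np.ndarray, label: ALineLabel | int) -> list[float]:
    """Arc angle (degrees) of each contiguous same-class run in one frame."""
    frame_labels = np.asarray(frame_labels)
    n_theta = frame_labels.size
    runs = circular_runs(frame_labels == int(label))
    return [length * 360.0 / n_theta for _, length in runs]


def plaque_length(
    enface_labels: np.ndarray, label: ALineLabel | int, frame_interval_mm: float
) -> list[list[float]]:
    """Per-θ-line plaque lengths (mm): contiguous frame runs × frame interval.

    z is linear (the pullback has ends), so runs do not wrap.
    """
    if frame_interval_mm <= 0:
        raise ValueError("frame interval must be positive")
    enface_labels = np.asarray(enface_labels)
    out: list[list[float]] = []
    for t in range(enface_labels.shape[0]):
        flags = enface_labels[t] == int(label)
        lengths: list[float] = []
        count = 0
        for f in flags:
            if f:
                count += 1
            elif count:
                lengths.append(count * frame_interval_mm)
                count = 0
        if count:
            lengths.append(count * frame_interval_mm)
        out.append(lengths)
    return out


def bland_altman(
    predicted: np.ndarray, reference: np.ndarray
) -> dict[str, float | np.ndarray]:
    """Bland–Altman agreement: bias, SD, and 95% limits of (pred − ref).

    Also returns the plot data (per-pair mean vs. difference).
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.size < 2:
        raise ValueError("need at least 2 aligned measurement pairs")
    diff = predicted - reference
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return {
        "bias": bias,
        "sd": sd,
        "lower_limit": bias - 1.96 * sd,
        "upper_limit": bias + 1.96 * sd,
        "means": (predicted + reference) / 2.0,
        "differences": diff,
    }


def paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired metric vectors.

    Exact null distribution for n ≤ 25 (no ties/zeros), normal approximation
    otherwise; identical vectors give the degenerate p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    method = "exact" if a.size <= 25 else "approx"
    try:
        result = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    except ValueError:
        result = stats.wilcoxon(a, b, alternative="two-sided", method="approx")
    return float(result.pvalue)


def make_folds(
    voi_ids: list[str],
    n_folds: int = 5,
    held_out_fraction: float = 0.0,
    seed: int = 0,
    n_validation_subsets: int = 1,
    n_test_subsets: int = 1,
) -> FoldSplit:
    """VOI-granularity cross-validation split.

    VOIs (never frames) are shuffled, a held-out fraction is removed, and the
    rest is divided into ``n_folds`` subsets.  Fold i uses subset i for
    testing, the next subset for validation, and the remaining subsets for
    training, rotating so every subset is the test set exactly once.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    ids = list(voi_ids)
    rng.shuffle(ids)
    n_held = int(round(held_out_fraction * len(ids)))
    held_out = sorted(ids[:n_held])
    pooled = ids[n_held:]
    if len(pooled) < n_folds:
        raise ValueError(
            f"{len(pooled)} pooled VOIs cannot fill {n_folds} folds"
        )
    subsets = [sorted(pooled[i::n_folds]) for i in range(n_folds)]
    folds = []
    for i in range(n_folds):
        test = subsets[i]
        val = [v for j in range(1, 1 + n_validation_subsets) for v in subsets[(i + j) % n_folds]]
        train = [
            v
            for j in range(n_folds)
            if j != i and j not in [(i + k) % n_folds for k in range(1, 1 + n_validation_subsets)]
            for v in subsets[j]
        ]
        folds.append({"train": train, "validation": val, "test": test})
    split = FoldSplit(folds=folds, held_out=held_out)
    split.validate()
    return split


def select_folds_for_relabeling(
    fold_mean_f1: list[float], threshold: float = 0.7
) -> list[int]:
    """Indices of folds whose mean F1 is strictly below the threshold.

    Flags folds for manual label review; never mutates labels itself.
    """
    return [i for i, f1 in enumerate(fold_mean_f1) if f1 < threshold]
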