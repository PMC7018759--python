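"""Hybrid random-forest A-line classifier.

The 100 convolutional features (penultimate CNN activations) and the lumen
morphology features are concatenated — CNN block first — and classified with
a random forest.  The forest size is tunable from the out-of-bag (OOB) error
curve over a 100..1000 grid in steps of 50; the published configuration uses
250 trees and 16 candidate variables per split, and the OOB curve plateaus
near that size.  Class probabilities are tree-vote fractions, which feed the
CRF unary potentials downstream.

Trees are scale-invariant, so no feature scaling is applied, and class
imbalance is handled only upstream in the CNN loss weighting — the forest
trains on raw counts.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "assemble_hybrid_features",
    "tune_rf_oob",
    "HybridForestClassifier",
    "DEFAULT_TREE_GRID",
]

DEFAULT_TREE_GRID = tuple(range(100, 1001, 50))


def assemble_hybrid_features(
    cnn_features: np.ndarray, morph_features: np.ndarray
) -> np.ndarray:
    """Concatenate per-A-line CNN (first) and morphology feature blocks."""
    cnn_features = np.atleast_2d(cnn_features)
    morph_features = np.atleast_2d(morph_features)
    if cnn_features.shape[0] != morph_features.shape[0]:
        raise ValueError(
            f"row mismatch: {cnn_features.shape[0]} CNN vs "
            f"{morph_features.shape[0]} morphology rows"
        )
    return np.concatenate([cnn_features, morph_features], axis=1)


def tune_rf_oob(
    features: np.ndarray,
    labels: np.ndarray,
    tree_grid: tuple = DEFAULT_TREE_GRID,
    n_variables_per_split: int = 16,
    plateau_tolerance: float = 0.002,
    random_state: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the forest size from the OOB error curve.

    Fits one forest per grid point (warm-started tree growth, so the total
    cost is that of the largest forest), records the OOB error, and returns
    the smallest grid size whose OOB error is within ``plateau_tolerance`` of
    the curve minimum, together with the full curve.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("OOB tuning needs at least two classes")
    grid = sorted(tree_grid)
    forest = RandomForestClassifier(
        n_estimators=grid[0],
        max_features=n_variables_per_split,
        oob_score=True,
        bootstrap=True,
        warm_start=True,
        random_state=random_state,
        n_jobs=1,
    )
    errors = []
    for n_trees in grid:
        forest.set_params(n_estimators=n_trees)
        forest.fit(features, labels)
        errors.append(1.0 - forest.oob_score_)
    errors = np.asarray(errors)
    chosen = grid[int(np.argmax(errors <= errors.min() + plateau_tolerance))]
    return chosen, errors


class HybridForestClassifier(ClassifierMixin, BaseEstimator):
    """Random forest over hybrid (convolutional + morphology) features.

    A thin estimator around :class:`sklearn.ensemble.RandomForestClassifier`
    that pins the published defaults (250 trees, 16 variables per split),
    optionally re-tunes the tree count from the OOB curve at fit time, and
    records feature names and importances for reporting.
    """

    def __init__(
        self,
        n_trees: int = 250,
        n_variables_per_split: int = 16,
        tune_trees: bool = False,
        tree_grid: tuple = DEFAULT_TREE_GRID,
        plateau_tolerance: float = 0.002,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.n_variables_per_split = n_variables_per_split
        self.tune_trees = tune_trees
        self.tree_grid = tree_grid
        self.plateau_tolerance = plateau_tolerance
        self.random_state = random_state

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("training labels contain a single class")
        max_features = min(self.n_variables_per_split, X.shape[1])
        n_trees = self.n_trees
        if self.tune_trees:
            n_trees, self.oob_curve_ = tune_rf_oob(
                X,
                y,
                tree_grid=self.tree_grid,
                n_variables_per_split=max_features,
                plateau_tolerance=self.plateau_tolerance,
                random_state=self.random_state,
            )
        self.n_trees_ = n_trees
        self.forest_ = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            oob_score=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        self.oob_score_ = float(self.forest_.oob_score_)
        self.feature_importances_ = self.forest_.feature_importances_
        self.feature_names_ = (
            list(feature_names)
            if feature_names is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
        if len(self.feature_names_) != X.shape[1]:
            raise ValueError("feature_names length does not match feature dimension")
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Tree-vote fractions per class; rows sum to 1 exactly."""
        return self.forest_.predict_proba(np.asarray(X))

    def predict(self, X) -> np.ndarray:
        return self.forest_.predict(np.asarray(X))

    def manifest(self) -> dict:
        return {
            "n_trees": int(self.n_trees_),
            "mtry": int(self.forest_.max_features),
            "random_state": self.random_state,
            "oob_score": self.oob_score_,
            "feature_names": self.feature_names_,
            "importances": [float(v) for v in self.feature_importances_],
        }
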