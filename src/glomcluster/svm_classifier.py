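"""Cell-class prediction from six easily attainable parameters.

A C-classification SVM with a radial kernel (cost 100, gamma 0.01) is
trained on five physiological parameters (early AHP score, input
resistance, AP speed ratio, AP half-width, AP amplitude) plus one
morphological parameter (the 2D convex-hull area), with class labels taken
from the morphological clustering.  The data are split 85/15 into
stratified training and test sets and features are z-scored with training
statistics only — the chosen RBF hyperparameters are scale-sensitive, so
scaling is a fixed part of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

__all__ = ["ClassifierSpec", "TrainedClassifier", "train", "predict"]

DEFAULT_FEATURES = (
    "early_ahp",
    "input_resistance",
    "speed_ratio",
    "half_width",
    "amplitude",
    "hull2d_area",
)


@dataclass(frozen=True)
class ClassifierSpec:
    features: tuple[str, ...] = DEFAULT_FEATURES
    kernel: str = "rbf"
    cost: float = 100.0
    gamma: float = 0.01
    train_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train fraction must be in (0, 1)")


@dataclass
class TrainedClassifier:
    model: SVC
    feature_names: tuple[str, ...]
    scale_mean: np.ndarray      # training-split statistics only
    scale_sd: np.ndarray
    classes: np.ndarray
    test_accuracy: float
    train_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    test_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _feature_matrix(table: pd.DataFrame, features: tuple[str, ...]) -> np.ndarray:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"missing classifier features: {missing}")
    return table.loc[:, list(features)].to_numpy(dtype=float)


def train(table: pd.DataFrame, labels: np.ndarray,
          spec: ClassifierSpec = ClassifierSpec()) -> TrainedClassifier:
    """Fit the classifier on a stratified train split and report held-out accuracy.

    The split is re-drawn (up to 100 attempts) if any class is absent from
    the training set; a single-class input raises immediately.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training needs at least two classes")
    X = _feature_matrix(table, spec.features)
    train_idx = test_idx = None
    for attempt in range(100):
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=spec.train_fraction, random_state=spec.seed + attempt
        )
        tr, te = next(splitter.split(X, y))
        if set(np.unique(y[tr])) == set(classes):
            train_idx, test_idx = tr, te
            break
    if train_idx is None:
        raise ValueError("could not draw a training split containing every class")
    mean = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    model = SVC(kernel=spec.kernel, C=spec.cost, gamma=spec.gamma)
    model.fit(Xs[train_idx], y[train_idx])
    accuracy = float(np.mean(model.predict(Xs[test_idx]) == y[test_idx])) if len(test_idx) else np.nan
    return TrainedClassifier(
        model=model,
        feature_names=spec.features,
        scale_mean=mean,
        scale_sd=sd,
        classes=classes,
        test_accuracy=accuracy,
        train_index=train_idx,
        test_index=test_idx,
    )


def predict(classifier: TrainedClassifier, table: pd.DataFrame) -> pd.DataFrame:
    """Predict one class per cell; deterministic given the model.

    Returns a per-cell decision record: the predicted class and the decision-
    function margins against every class.
    """
    X = _feature_matrix(table, classifier.feature_names)
    Xs = (X - classifier.scale_mean) / classifier.scale_sd
    pred = classifier.model.predict(Xs)
    decision = classifier.model.decision_function(Xs)
    if decision.ndim == 1:
        decision = decision[:, None]
    out = pd.DataFrame({"predicted_class": pred}, index=table.index)
    for j in range(decision.shape[1]):
        out[f"decision_{j}"] = decision[:, j]
    return out
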