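"""Classical-ML baselines: hand-crafted features x shallow classifiers.

Three feature representations — raw unrolled pixels, histograms of oriented
gradients (HOG), and uniform local binary patterns (LBP) — feed a roster of
shallow classifiers (SVM, MLP, random forest, decision tree, Gaussian naive
Bayes, k-NN, plus AdaBoost and QDA kept out of headline reports).  Frames
are downscaled to a small square input (32 or 64 px) by area averaging
before feature extraction.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from PIL import Image
from skimage.feature import hog as _sk_hog
from skimage.feature import local_binary_pattern

from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .geometry import EyeLabel, LABEL_ORDER

__all__ = [
    "FeatureConfig",
    "ClassifierConfig",
    "EvalReport",
    "resize_frame",
    "unroll_normalize",
    "hog_features",
    "lbp_features",
    "extract_features",
    "train_classifier",
    "evaluate",
]

FEATURE_KINDS = ("unrolled", "hog", "lbp")
CLASSIFIER_KINDS = (
    "svm",
    "mlp",
    "random_forest",
    "decision_tree",
    "gaussian_nb",
    "knn",
    "adaboost",
    "qda",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature representation and its layout parameters.

    HOG uses 8 unsigned orientations over 4x4-pixel cells with 1x1-cell
    blocks; LBP uses radius 5 with 100 sample points, histogrammed over the
    102 uniform-pattern bins.
    """

    kind: str = "unrolled"
    input_side: int = 32
    hog_orientations: int = 8
    hog_cell: int = 4
    lbp_radius: int = 5
    lbp_points: int = 100

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.input_side < 16:
            raise ValueError("input_side must be >= 16")
        if self.kind == "hog" and self.input_side % self.hog_cell != 0:
            raise ValueError(
                f"HOG cell size {self.hog_cell} must divide input_side {self.input_side}"
            )
        if self.kind == "lbp" and self.input_side <= 2 * self.lbp_radius:
            raise ValueError("image too small for the LBP radius")

    @property
    def length(self) -> int:
        if self.kind == "unrolled":
            return self.input_side ** 2
        if self.kind == "hog":
            n_cells = self.input_side // self.hog_cell
            return self.hog_orientations * n_cells ** 2
        return self.lbp_points + 2


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier choice and hyperparameters (defaults as benchmarked).

    SVM: RBF kernel, C = 1.0, gamma = 1e-3.  MLP: one hidden layer of 100
    ReLU units, Adam.  Random forest: 100 trees, Gini.  Gaussian NB:
    variance smoothing 1e-9.  k-NN: k = 3, uniform weights.
    """

    kind: str = "svm"
    seed: int = 0
    svm_c: float = 1.0
    svm_gamma: float = 1e-3
    mlp_hidden: int = 100
    rf_trees: int = 100
    nb_smoothing: float = 1e-9
    knn_k: int = 3

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")

    def build(self):
        """Instantiate the scikit-learn estimator."""
        if self.kind == "svm":
            return SVC(kernel="rbf", C=self.svm_c, gamma=self.svm_gamma,
                       random_state=self.seed)
        if self.kind == "mlp":
            return MLPClassifier(hidden_layer_sizes=(self.mlp_hidden,),
                                 activation="relu", solver="adam",
                                 random_state=self.seed, max_iter=500)
        if self.kind == "random_forest":
            return RandomForestClassifier(n_estimators=self.rf_trees,
                                          criterion="gini", random_state=self.seed)
        if self.kind == "decision_tree":
            return DecisionTreeClassifier(criterion="gini", random_state=self.seed)
        if self.kind == "gaussian_nb":
            return GaussianNB(var_smoothing=self.nb_smoothing)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k, weights="uniform")
        if self.kind == "adaboost":
            return AdaBoostClassifier(random_state=self.seed)
        return QuadraticDiscriminantAnalysis()


@dataclass
class EvalReport:
    """Held-out evaluation: accuracy, per-class confusion, timing."""

    accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted, LABEL_ORDER
    labels: List[str]
    feature: FeatureConfig
    classifier: ClassifierConfig
    mean_predict_s: float = 0.0

    def to_dict(self) -> Dict:
        return {
            "accuracy": self.accuracy,
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "feature": {"kind": self.feature.kind, "input_side": self.feature.input_side},
            "classifier": {"kind": self.classifier.kind, "seed": self.classifier.seed},
            "mean_predict_s": self.mean_predict_s,
        }


def resize_frame(frame: np.ndarray, side: int) -> np.ndarray:
    """Downscale (area averaging) a square grayscale frame to side x side."""
    img = Image.fromarray(frame, mode="L")
    return np.asarray(img.resize((side, side), Image.BOX))


def unroll_normalize(frame: np.ndarray, side: int) -> np.ndarray:
    """Row-major flatten of the resized frame, scaled to [0, 1]."""
    small = frame if frame.shape == (side, side) else resize_frame(frame, side)
    return small.astype(np.float64).ravel() / 255.0


def hog_features(frame: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Unsigned-gradient orientation histograms, 8 bins per 4x4 cell."""
    side = config.input_side
    if side % config.hog_cell != 0:
        raise ValueError("HOG cell must divide the input side")
    small = frame if frame.shape == (side, side) else resize_frame(frame, side)
    return _sk_hog(
        small,
        orientations=config.hog_orientations,
        pixels_per_cell=(config.hog_cell, config.hog_cell),
        cells_per_block=(1, 1),
        block_norm="L2",
        feature_vector=True,
    )


def lbp_features(frame: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Uniform-pattern LBP histogram (P + 2 bins, normalized to sum 1)."""
    side = config.input_side
    if side <= 2 * config.lbp_radius:
        raise ValueError("image too small for the LBP radius")
    small = frame if frame.shape == (side, side) else resize_frame(frame, side)
    codes = local_binary_pattern(
        small, P=config.lbp_points, R=config.lbp_radius, method="uniform"
    )
    # drop the border band whose sampling circle leaves the image
    r = config.lbp_radius
    valid = codes[r:-r, r:-r]
    hist, _ = np.histogram(valid, bins=np.arange(config.lbp_points + 3) - 0.5)
    return hist.astype(np.float64) / hist.sum()


def extract_features(frame: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Dispatch a frame to the configured representation."""
    small = resize_frame(frame, config.input_side)
    if config.kind == "unrolled":
        return unroll_normalize(small, config.input_side)
    if config.kind == "hog":
        return hog_features(small, config)
    return lbp_features(small, config)


def features_matrix(frames: Sequence[np.ndarray], config: FeatureConfig) -> np.ndarray:
    return np.stack([extract_features(f, config) for f in frames])


def train_classifier(
    features: np.ndarray, labels: Sequence[EyeLabel], config: ClassifierConfig
):
    """Fit the configured classifier; deterministic for a fixed seed.

    Raises ``ValueError`` on a single-class training set or on rows of
    inconsistent dimensionality (rejected by the estimator itself).
    """
    y = np.array([l.value if isinstance(l, EyeLabel) else str(l) for l in labels])
    if len(set(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be a (n_samples, n_features) matrix "
                         "matching the label count")
    model = config.build()
    model.fit(X, y)
    return model


def evaluate(
    model,
    features: np.ndarray,
    labels: Sequence[EyeLabel],
    feature_config: FeatureConfig,
    classifier_config: ClassifierConfig,
    time_predictions: bool = False,
) -> EvalReport:
    """Confusion matrix and accuracy on a labeled feature matrix.

    With ``time_predictions`` each row is predicted individually with a
    monotonic clock so downstream latency scoring can reuse the timings.
    """
    from sklearn.metrics import confusion_matrix

    X = np.asarray(features, dtype=np.float64)
    y_true = np.array([l.value if isinstance(l, EyeLabel) else str(l) for l in labels])
    if X.shape[1] != getattr(model, "n_features_in_", X.shape[1]):
        raise ValueError(
            f"feature dimensionality {X.shape[1]} does not match the model "
            f"({model.n_features_in_})"
        )
    mean_t = 0.0
    if time_predictions:
        preds = []
        times = []
        for row in X:
            t0 = time.perf_counter()
            preds.append(model.predict(row[None, :])[0])
            times.append(time.perf_counter() - t0)
        y_pred = np.array(preds)
        mean_t = float(np.mean(times))
    else:
        y_pred = model.predict(X)
    names = [l.value for l in LABEL_ORDER]
    cm = confusion_matrix(y_true, y_pred, labels=names)
    acc = float((y_true == y_pred).mean())
    return EvalReport(
        accuracy=acc,
        confusion=cm,
        labels=names,
        feature=feature_config,
        classifier=classifier_config,
        mean_predict_s=mean_t,
    )
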