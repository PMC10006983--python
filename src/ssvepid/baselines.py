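"""Comparator classifiers: linear SVM and kNN on the same FBCSP features.

Both sit behind the same ``fit(X, y)`` / ``predict(X)`` surface as the DFN
so the evaluation machinery treats the three interchangeably.  The SVM is a
linear-kernel SVC in a one-vs-rest wrapper (C = 1.0 by default).  The kNN
uses Euclidean distance with a declared deterministic tie-break: majority
vote, ties resolved by the smaller mean neighbour distance, then by the
lower class label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .errors import InvalidConfigError, InvalidInputError

__all__ = ["BaselineConfig", "LinearSVMClassifier", "KNNClassifier", "fit_linear_svm", "fit_knn"]


@dataclass
class BaselineConfig:
    svm_regularization: float = 1.0
    svm_multiclass: str = "one-vs-rest"
    knn_k: int = 1
    knn_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.svm_regularization <= 0:
            raise InvalidConfigError("svm_regularization must be positive")
        if self.svm_multiclass != "one-vs-rest":
            raise InvalidConfigError("only one-vs-rest multiclass SVM is supported")
        if self.knn_k < 1:
            raise InvalidConfigError("knn_k must be >= 1")
        if self.knn_metric != "euclidean":
            raise InvalidConfigError("only euclidean kNN metric is supported")


class LinearSVMClassifier:
    """One-vs-rest linear-kernel SVM (deterministic: convex problem)."""

    def __init__(self, config: BaselineConfig | None = None):
        self.config = config or BaselineConfig()
        self._clf = OneVsRestClassifier(
            SVC(kernel="linear", C=self.config.svm_regularization)
        )

    def fit(self, x: np.ndarray, y: np.ndarray, blocks=None):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise InvalidInputError("SVM needs at least two classes")
        self._clf.fit(np.asarray(x), y)
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return self._clf.decision_function(np.asarray(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._clf.predict(np.asarray(x))


class KNNClassifier:
    """k-nearest-neighbour vote with declared tie-breaking."""

    def __init__(self, config: BaselineConfig | None = None):
        self.config = config or BaselineConfig()
        self._nn: NearestNeighbors | None = None
        self._y: np.ndarray | None = None

    def fit(self, x: np.ndarray, y: np.ndarray, blocks=None):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y)
        if self.config.knn_k > len(y):
            raise InvalidConfigError(
                f"k={self.config.knn_k} exceeds training-set size {len(y)}"
            )
        self._nn = NearestNeighbors(n_neighbors=self.config.knn_k, metric="euclidean")
        self._nn.fit(x)
        self._y = y
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._nn is None:
            raise InvalidInputError("classifier not fitted")
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        dist, idx = self._nn.kneighbors(x)
        out = []
        for d_row, i_row in zip(dist, idx):
            labels = self._y[i_row]
            candidates = {}
            for lab in np.unique(labels):
                mask = labels == lab
                candidates[lab] = (-int(mask.sum()), float(d_row[mask].mean()), lab)
            # most votes, then smallest mean distance, then lowest label
            out.append(min(candidates.values())[2])
        return np.array(out)


def fit_linear_svm(
    features: np.ndarray, labels: np.ndarray, config: BaselineConfig | None = None
) -> LinearSVMClassifier:
    """Fit the SVM-FBCSP comparator."""
    return LinearSVMClassifier(config).fit(features, labels)


def fit_knn(
    features: np.ndarray, labels: np.ndarray, config: BaselineConfig | None = None
) -> KNNClassifier:
    """Fit the kNN-FBCSP comparator."""
    return KNNClassifier(config).fit(features, labels)
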