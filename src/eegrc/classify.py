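"""Pairwise kernel-SVM classification under frame-level leave-one-out CV.

Every classification here is a two-class problem (one pair of mental tasks).
The protocol is frame-level leave-one-out: each frame in turn is held out,
an SVM is trained on all remaining frames, and overall accuracy (percent)
is the fraction of held-out frames predicted correctly.  Note that frames
from one session overlap by 50%, so frame-level LOOCV shares samples
between train and test folds; a session-level grouping option
(``group_by_session=True``) holds out whole sessions instead, but the
frame-level protocol is the default.

Kernels: linear, quadratic ((x.x' + 1)^2), polynomial ((x.x' + 1)^d,
default degree 3) and RBF (scale 1 / (n_features * var(X)) unless given).
The quadratic-programming solver behind the SVM is scikit-learn's SVC; this
module owns only kernel configuration, the CV protocol and the accuracy
accounting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .reflection import FeatureMatrix

__all__ = [
    "KernelSpec",
    "CVResult",
    "loocv_classify",
    "pca_reduce",
    "ranksum_separability",
]

KERNEL_KINDS = ("linear", "quadratic", "polynomial", "rbf")


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel configuration.

    ``quadratic`` is polynomial with degree fixed at 2; ``degree`` applies to
    the polynomial kernel only (default 3); ``gamma`` is the RBF scale
    (default: 1 / (n_features * var(X)), sklearn's "scale"); ``C`` is the
    soft-margin penalty.
    """

    kind: str = "quadratic"
    degree: int = 3
    gamma: float | None = None
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}")
        if self.kind == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if not self.C > 0:
            raise ValueError("soft-margin penalty C must be positive")

    def build(self) -> SVC:
        if self.kind == "linear":
            return SVC(kernel="linear", C=self.C)
        if self.kind == "quadratic":
            return SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0, C=self.C)
        if self.kind == "polynomial":
            return SVC(kernel="poly", degree=self.degree, gamma=1.0, coef0=1.0,
                       C=self.C)
        gamma = "scale" if self.gamma is None else self.gamma
        return SVC(kernel="rbf", gamma=gamma, C=self.C)


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validated pairwise classification."""

    predicted: tuple
    truth: tuple
    kernel: KernelSpec
    grouped_by_session: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.truth)

    @property
    def accuracy(self) -> float:
        """Percent of frames predicted correctly, in [0, 100]."""
        correct = sum(p == t for p, t in zip(self.predicted, self.truth))
        return 100.0 * correct / self.n_frames

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "accuracy": self.accuracy,
                "n_frames": self.n_frames,
                "kernel": {"kind": self.kernel.kind, "degree": self.kernel.degree,
                           "C": self.kernel.C, "gamma": self.kernel.gamma},
                "grouped_by_session": self.grouped_by_session,
                "predicted": list(self.predicted),
                "truth": list(self.truth),
            }, fh, indent=2)


def _predict_binary(clf: SVC, X: np.ndarray) -> np.ndarray:
    """Predict with a deterministic tie-break at the margin.

    ``classes_`` is sorted, so a decision value of exactly zero maps to the
    lexicographically smaller label.
    """
    dec = clf.decision_function(X)
    return np.where(dec > 0, clf.classes_[1], clf.classes_[0])


def loocv_classify(
    features: FeatureMatrix,
    kernel: KernelSpec | None = None,
    group_by_session: bool = False,
) -> CVResult:
    """Leave-one-out cross-validated SVM accuracy for a two-class FeatureMatrix.

    Each frame (or, with ``group_by_session``, each session) is tested with
    all remaining frames as training data; accuracy is the percentage of
    correctly classified frames over all folds.
    """
    kernel = kernel or KernelSpec()
    X = features.values
    y = np.asarray(features.labels)
    classes = sorted(set(features.labels))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 frames per class, got {counts}")

    if group_by_session:
        sessions = np.asarray(features.sessions)
        if sessions.size != len(y):
            raise ValueError("session ids required for session-level grouping")
        fold_masks = [sessions == s for s in dict.fromkeys(features.sessions)]
    else:
        fold_masks = [np.arange(len(y)) == i for i in range(len(y))]

    predicted = np.empty(len(y), dtype=y.dtype)
    for test_mask in fold_masks:
        train = ~test_mask
        if len(set(y[train])) < 2:
            raise ValueError("a fold left fewer than two classes in training")
        clf = kernel.build()
        clf.fit(X[train], y[train])
        predicted[test_mask] = _predict_binary(clf, X[test_mask])
    return CVResult(predicted=tuple(predicted), truth=tuple(y),
                    kernel=kernel, grouped_by_session=group_by_session)


def pca_reduce(features: FeatureMatrix, n_components: int) -> FeatureMatrix:
    """Project a FeatureMatrix onto its leading principal components.

    Components are scores of the mean-centred matrix, ordered by decreasing
    explained variance; columns are named "pc1", "pc2", ...
    """
    if not 1 <= n_components <= features.n_features:
        raise ValueError(
            f"n_components must be in [1, {features.n_features}], got {n_components}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(features.values)
    import pandas as pd

    return FeatureMatrix(
        features=pd.DataFrame(scores,
                              columns=[f"pc{i + 1}" for i in range(n_components)]),
        labels=features.labels,
        sessions=features.sessions,
    )


def ranksum_separability(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for class separability of a feature.

    Small p-values indicate the two task classes have different medians in
    this feature, i.e. the feature separates the pair.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(_stats.ranksums(a, b).pvalue)
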