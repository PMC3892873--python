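"""Static-posture max-margin classifiers and posture-based fall risk.

Three postures matter for toddler fall risk: the push-up climb (pushing off a
low object by the hands), the pull-up climb (pulling up on a high object) and
sitting.  Each is a binary soft-margin SVM over the z-scored 60-dimensional
joint-coordinate vector with an inhomogeneous quadratic kernel
K(x, x') = (x.x' + 1)^2.  The signed decision-function value d acts as a
classification confidence; the positive side is mapped to a fall risk by the
saturating map p = 1 - exp(-d^2 / alpha).  A greedy backward feature
elimination (drop the single feature whose removal most improves
cross-validated accuracy, repeat until no strict improvement) prunes
redundant feature dimensions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .skeleton import (FEATURE_DIM, NormalizationStats, SkeletonFrame,
                       frame_feature_vector, normalize)


@dataclass
class TrainingSet:
    """Labelled posture frames: X (n, d) raw feature vectors, y in {-1, +1}."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y length mismatch")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be in {-1, +1}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip((int(v) for v in vals), (int(c) for c in counts)))


def _poly_kernel(A: np.ndarray, B: np.ndarray, degree: int) -> np.ndarray:
    return (A @ B.T + 1.0) ** degree


@dataclass
class PostureModel:
    """A trained posture SVM in dual form.

    Stores the support vectors (already normalized and masked), the signed
    dual coefficients alpha_j * y_j, the bias, the kernel degree, the feature
    mask over the 60 dimensions and the normalization statistics, so the
    decision function f(x) = sum_j alpha_j y_j K(s_j, x) + b can be evaluated
    without the training library.
    """

    support_vectors: np.ndarray       # (n_sv, n_masked)
    dual_coef: np.ndarray             # (n_sv,)  alpha_j * y_j
    intercept: float
    kernel_degree: int
    feature_mask: np.ndarray          # (d,) bool over raw feature dims
    norm_stats: NormalizationStats
    C: float = 1.0
    posture: Optional[str] = None

    def __post_init__(self) -> None:
        self.support_vectors = np.atleast_2d(np.asarray(self.support_vectors, dtype=float))
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()
        self.feature_mask = np.asarray(self.feature_mask, dtype=bool)

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        x = normalize(x, self.norm_stats)
        return x[:, self.feature_mask]

    def decision_distances(self, X: np.ndarray) -> np.ndarray:
        """Signed decision-function values for raw (n, 60) feature rows."""
        Z = self._prepare(X)
        K = _poly_kernel(Z, self.support_vectors, self.kernel_degree)
        return K @ self.dual_coef + self.intercept

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "posture": self.posture,
            "kernel": {"type": "poly", "degree": self.kernel_degree, "coef0": 1.0},
            "C": self.C,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "feature_mask": self.feature_mask.astype(int).tolist(),
            "norm_mean": self.norm_stats.mean.tolist(),
            "norm_std": self.norm_stats.std.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PostureModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            support_vectors=np.asarray(payload["support_vectors"]),
            dual_coef=np.asarray(payload["dual_coef"]),
            intercept=float(payload["intercept"]),
            kernel_degree=int(payload["kernel"]["degree"]),
            feature_mask=np.asarray(payload["feature_mask"], dtype=bool),
            norm_stats=NormalizationStats(np.asarray(payload["norm_mean"]),
                                          np.asarray(payload["norm_std"])),
            C=float(payload["C"]),
            posture=payload.get("posture"),
        )


def train_posture(train: TrainingSet, kernel_degree: int = 2, C: float = 1.0,
                  feature_mask: Optional[np.ndarray] = None,
                  posture: Optional[str] = None) -> PostureModel:
    """Fit a soft-margin SVM with the kernel K(x, x') = (x.x' + 1)^degree.

    Normalization statistics are fitted on the training features and stored in
    the model; ``feature_mask`` restricts the classifier to a subset of
    dimensions (default: all).
    """
    counts = train.class_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present in the training set")
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 examples per class")
    d = train.X.shape[1]
    mask = np.ones(d, dtype=bool) if feature_mask is None else \
        np.asarray(feature_mask, dtype=bool)
    stats = NormalizationStats.fit(train.X)
    Z = normalize(train.X, stats)[:, mask]
    svc = SVC(kernel="poly", degree=kernel_degree, gamma=1.0, coef0=1.0, C=C)
    svc.fit(Z, train.y)
    # sklearn orders classes as [-1, +1], so decision > 0 <=> predicted +1.
    return PostureModel(
        support_vectors=svc.support_vectors_,
        dual_coef=svc.dual_coef_[0],
        intercept=float(svc.intercept_[0]),
        kernel_degree=kernel_degree,
        feature_mask=mask,
        norm_stats=stats,
        C=C,
        posture=posture,
    )


def decision_distance(model: PostureModel, x: np.ndarray) -> float:
    """Signed confidence distance of one raw feature vector to the hyperplane.

    This is the unnormalized functional margin f(x); its scale is absorbed by
    the module's local alpha during calibration.
    """
    return float(model.decision_distances(np.atleast_2d(x))[0])


def risk_from_distance(d: Union[float, np.ndarray], alpha: float) -> Union[float, np.ndarray]:
    """Map a signed confidence distance to a fall risk in [0, 1).

    p = 1 - exp(-d^2 / alpha) on the posture's positive side (d > 0), zero
    otherwise.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d = np.asarray(d, dtype=float)
    p = np.where(d > 0, -np.expm1(-np.square(d) / alpha), 0.0)
    return float(p) if p.ndim == 0 else p


def detect_sitting(model: PostureModel, frame: SkeletonFrame) -> bool:
    """True iff the sitting classifier's decision function is positive.

    A positive result gates off the body-sway and foot-altitude modules.
    """
    return decision_distance(model, frame_feature_vector(frame)) > 0


def _cv_accuracy(X: np.ndarray, y: np.ndarray, mask: np.ndarray, folds: int,
                 seed: int, kernel_degree: int, C: float) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        stats = NormalizationStats.fit(X[train_idx])
        Ztr = normalize(X[train_idx], stats)[:, mask]
        Zte = normalize(X[test_idx], stats)[:, mask]
        svc = SVC(kernel="poly", degree=kernel_degree, gamma=1.0, coef0=1.0, C=C)
        svc.fit(Ztr, y[train_idx])
        correct += int(np.count_nonzero(svc.predict(Zte) == y[test_idx]))
    return correct / X.shape[0]


@dataclass
class EliminationResult:
    feature_mask: np.ndarray
    initial_accuracy: float
    final_accuracy: float
    removed: list[int] = field(default_factory=list)


def backward_feature_elimination(train: TrainingSet, folds: int = 5,
                                 seed: int = 0, kernel_degree: int = 2,
                                 C: float = 1.0) -> EliminationResult:
    """Greedy wrapper feature selection by cross-validated accuracy.

    At each step every remaining feature is tentatively removed; the removal
    giving the best strict CV-accuracy improvement is committed (ties broken
    towards the lowest feature index).  Stops when no single removal improves
    accuracy, so the final CV accuracy is never below the initial one.
    """
    X, y = train.X, train.y
    n_per_class = min(train.class_counts().values())
    if n_per_class < folds:
        raise ValueError("cross-validation infeasible: fewer samples than folds")
    d = X.shape[1]
    mask = np.ones(d, dtype=bool)
    current = _cv_accuracy(X, y, mask, folds, seed, kernel_degree, C)
    initial = current
    removed: list[int] = []
    while mask.sum() > 1:
        best_gain, best_feat, best_acc = 0.0, None, current
        for feat in np.flatnonzero(mask):
            trial = mask.copy()
            trial[feat] = False
            acc = _cv_accuracy(X, y, trial, folds, seed, kernel_degree, C)
            if acc - current > best_gain:
                best_gain, best_feat, best_acc = acc - current, int(feat), acc
        if best_feat is None:
            break
        mask[best_feat] = False
        removed.append(best_feat)
        current = best_acc
    return EliminationResult(mask, initial, current, removed)
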