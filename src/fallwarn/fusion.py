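"""Multi-modal fusion of the eight module risks into one alarm decision.

Two fusion schemes are provided.

**Weighted-mean thresholding.**  The module risks are sorted descending,
p_(1) >= ... >= p_(n), and combined with geometrically diminishing rank
weights controlled by beta in [0, 1):

    p_overall = [ p_(1)(1 - beta) + sum_{i=2..n} p_(i)(beta^{i-1} - beta^i) ]
                / (1 - beta^n)

beta = 0 recovers the maximum, beta -> 1 the arithmetic mean, and beta = 0.5
the halving weights 1/2, 1/4, 1/8, ...  The alarm fires when p_overall
strictly exceeds a user threshold T (0.5 by default).  beta is fitted to
expert labels by a recursive 1-D grid search on the mean absolute error.

**SVM classification.**  An RBF-kernel soft-margin classifier on the raw
8-vector of risks, with (C, gamma) chosen by a recursive 2-D grid search
maximizing k-fold cross-validated accuracy on the usual power-of-two
lattice.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .risks import MODULES, RiskVector


def rank_weights(n: int, beta: float) -> np.ndarray:
    """The normalized diminishing rank weights w_i, i = 1..n (sum to 1)."""
    if not 0.0 <= beta < 1.0:
        raise ValueError("beta must lie in [0, 1)")
    i = np.arange(1, n + 1)
    if beta == 0.0:
        w = np.zeros(n)
        w[0] = 1.0
        return w
    raw = beta ** (i - 1) - beta ** i
    return raw / (1.0 - beta ** n)


def _risk_array(risks: Union[RiskVector, np.ndarray, Sequence[float]]) -> np.ndarray:
    if isinstance(risks, RiskVector):
        return risks.p
    return np.asarray(risks, dtype=float)


def weighted_mean(risks: Union[RiskVector, np.ndarray, Sequence[float]],
                  beta: float) -> float:
    """Rank-weighted fusion of a risk vector (disabled modules enter as 0)."""
    p = np.sort(_risk_array(risks))[::-1]
    return float(p @ rank_weights(p.size, beta))


def alarm(overall: float, T: float = 0.5) -> bool:
    """Alarm decision: strictly greater than the threshold (ties: no alarm)."""
    if not 0.0 < T < 1.0:
        raise ValueError("T must lie in (0, 1)")
    return overall > T


def fit_beta(risk_matrix: np.ndarray, p_gt: np.ndarray,
             coarse_step: float = 0.01, refine_levels: int = 2
             ) -> tuple[float, float]:
    """Fit beta by recursive grid search on the mean absolute fitting error.

    A coarse sweep over [0, 0.99] at ``coarse_step`` is refined
    ``refine_levels`` times by re-gridding around the incumbent at a tenth of
    the step.  Deterministic; returns (beta, fit_error).
    """
    R = np.atleast_2d(np.asarray(risk_matrix, dtype=float))
    y = np.asarray(p_gt, dtype=float)
    if R.shape[0] != y.shape[0] or R.shape[0] < 2:
        raise ValueError("need >= 2 labelled risk vectors")
    S = -np.sort(-R, axis=1)  # rows sorted descending once

    def err(beta: float) -> float:
        w = rank_weights(S.shape[1], beta)
        return float(np.mean(np.abs(S @ w - y)))

    lo, hi, step = 0.0, 0.99, coarse_step
    best_beta, best_err = 0.0, np.inf
    for _ in range(refine_levels + 1):
        grid = np.arange(lo, hi + step / 2, step)
        grid = np.clip(grid, 0.0, 0.99)
        for b in grid:
            e = err(float(b))
            if e < best_err - 1e-15:
                best_err, best_beta = e, float(b)
        lo, hi = max(0.0, best_beta - step), min(0.99, best_beta + step)
        step /= 10.0
    return best_beta, best_err


@dataclass
class FusionModel:
    """A trained fusion stage: either (beta, T) or an RBF SVM with (C, gamma)."""

    scheme: str                       # "weighted_mean" | "svm"
    T: float = 0.5
    beta: Optional[float] = None
    fit_error: Optional[float] = None
    C: Optional[float] = None
    gamma: Optional[float] = None
    cv_accuracy: Optional[float] = None
    support_vectors: Optional[np.ndarray] = None
    dual_coef: Optional[np.ndarray] = None
    intercept: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scheme not in ("weighted_mean", "svm"):
            raise ValueError("scheme must be 'weighted_mean' or 'svm'")
        if self.scheme == "weighted_mean":
            if self.beta is None or not 0.0 <= self.beta < 1.0:
                raise ValueError("weighted_mean scheme requires beta in [0, 1)")
        if not 0.0 < self.T < 1.0:
            raise ValueError("T must lie in (0, 1)")

    def decision_value(self, risks: Union[RiskVector, np.ndarray]) -> float:
        """Overall risk (scheme 1) or signed SVM margin (scheme 2)."""
        x = _risk_array(risks)
        if self.scheme == "weighted_mean":
            return weighted_mean(x, self.beta)
        K = np.exp(-self.gamma * np.sum(
            np.square(self.support_vectors - x), axis=1))
        return float(K @ self.dual_coef + self.intercept)

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {"scheme": self.scheme, "T": self.T}
        if self.scheme == "weighted_mean":
            payload.update(beta=self.beta, fit_error=self.fit_error)
        else:
            payload.update(C=self.C, gamma=self.gamma,
                           cv_accuracy=self.cv_accuracy,
                           support_vectors=self.support_vectors.tolist(),
                           dual_coef=self.dual_coef.tolist(),
                           intercept=self.intercept)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FusionModel":
        payload = json.loads(Path(path).read_text())
        if payload["scheme"] == "weighted_mean":
            return cls(scheme="weighted_mean", T=payload["T"],
                       beta=payload["beta"], fit_error=payload.get("fit_error"))
        return cls(scheme="svm", T=payload["T"], C=payload["C"],
                   gamma=payload["gamma"], cv_accuracy=payload.get("cv_accuracy"),
                   support_vectors=np.asarray(payload["support_vectors"]),
                   dual_coef=np.asarray(payload["dual_coef"]),
                   intercept=float(payload["intercept"]))


def fit_weighted_mean_fusion(risk_matrix: np.ndarray, p_gt: np.ndarray,
                             T: float = 0.5) -> FusionModel:
    beta, err = fit_beta(risk_matrix, p_gt)
    return FusionModel(scheme="weighted_mean", T=T, beta=beta, fit_error=err)


def _cv_accuracy_svm(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                     folds: int, seed: int) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        svc = SVC(kernel="rbf", C=C, gamma=gamma)
        svc.fit(X[tr], y[tr])
        correct += int(np.count_nonzero(svc.predict(X[te]) == y[te]))
    return correct / X.shape[0]


def train_svm_fusion(risk_matrix: np.ndarray, p_gt: np.ndarray, T: float = 0.5,
                     folds: int = 5, seed: int = 0) -> FusionModel:
    """RBF-SVM fusion with a recursive (C, gamma) grid search.

    Labels are +1 where p_gt > T.  The coarse lattice is C = 2^-5..2^15,
    gamma = 2^-15..2^3 in steps of 2^2, refined once at step 2^0.5 around the
    incumbent; k-fold CV accuracy is the selection criterion (ties resolved
    towards the first grid point scanned, smaller exponents first).
    """
    X = np.atleast_2d(np.asarray(risk_matrix, dtype=float))
    y = np.where(np.asarray(p_gt, dtype=float) > T, 1, -1)
    if len(np.unique(y)) < 2:
        raise ValueError("both alarm classes must be present after thresholding")
    folds = min(folds, int(np.min(np.bincount((y + 1) // 2))))
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")

    best = (-np.inf, None, None)
    for logC in np.arange(-5.0, 15.0 + 1e-9, 2.0):
        for logG in np.arange(-15.0, 3.0 + 1e-9, 2.0):
            acc = _cv_accuracy_svm(X, y, 2.0 ** logC, 2.0 ** logG, folds, seed)
            if acc > best[0]:
                best = (acc, logC, logG)
    _, cC, cG = best
    for logC in np.arange(cC - 2.0, cC + 2.0 + 1e-9, 0.5):
        for logG in np.arange(cG - 2.0, cG + 2.0 + 1e-9, 0.5):
            acc = _cv_accuracy_svm(X, y, 2.0 ** logC, 2.0 ** logG, folds, seed)
            if acc > best[0]:
                best = (acc, logC, logG)
    cv_acc, logC, logG = best
    C, gamma = 2.0 ** logC, 2.0 ** logG
    svc = SVC(kernel="rbf", C=C, gamma=gamma)
    svc.fit(X, y)
    return FusionModel(scheme="svm", T=T, C=C, gamma=gamma, cv_accuracy=cv_acc,
                       support_vectors=svc.support_vectors_,
                       dual_coef=svc.dual_coef_[0],
                       intercept=float(svc.intercept_[0]))


def predict_alarm(model: FusionModel,
                  risks: Union[RiskVector, np.ndarray]) -> bool:
    """Boolean alarm for one risk vector under either fusion scheme."""
    if model.scheme == "weighted_mean":
        return alarm(model.decision_value(risks), model.T)
    return model.decision_value(risks) > 0.0
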