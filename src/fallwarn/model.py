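"""Model/Results facade over the full fall-risk pipeline.

:class:`FallRiskModel` is constructed from labelled skeleton clips plus the
scene context (floor plane, posture classifiers, local sigmoid scales);
``fit()`` trains the chosen fusion stage and returns a
:class:`FallRiskResults` carrying the fitted parameters, their fit
diagnostics, prediction methods and a ``summary()`` table.

:func:`run_synthetic_benchmark` wires the whole system together on generated
data -- floor-plane RANSAC, posture-SVM training, per-module alpha
calibration, fusion fitting on a training half and evaluation on a held-out
half -- and is the package's end-to-end reference experiment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import calibrate_all
from .evaluation import (ConfusionMatrix, Metrics, auc_trapezoid, confusion,
                         metrics, roc)
from .floor import FloorPlane, fit_floor_ransac
from .fusion import (FusionModel, fit_weighted_mean_fusion, predict_alarm,
                     train_svm_fusion, weighted_mean)
from .posture import PostureModel, train_posture
from .risks import MODULES, LocalParams, RiskVector, WindowConfig, clip_risk_vector
from .simulate import (DEFAULT_MIX, generate_calibration_set, generate_dataset,
                       generate_floor, posture_training_set)
from .skeleton import SkeletonClip


class FallRiskModel:
    """Fall-risk alarm model over labelled skeleton clips.

    Parameters
    ----------
    clips : sequence of SkeletonClip
        Training clips.
    p_gt : array-like
        Expert ground-truth risks in [0, 1], one per clip.
    plane : FloorPlane, optional
        Scene floor plane (default: the horizontal plane y = 0).
    posture_models : mapping, optional
        Trained posture SVMs under keys ``push_up_climb``, ``pull_up_climb``
        and ``sitting``; climb modules are disabled without them.
    params : LocalParams, optional
        Per-module sigmoid scales (default: the reference preset; prefer
        locally calibrated values).
    cfg : WindowConfig, optional
        Temporal window configuration.
    """

    def __init__(self, clips: Sequence[SkeletonClip], p_gt,
                 plane: Optional[FloorPlane] = None,
                 posture_models: Optional[Mapping[str, PostureModel]] = None,
                 params: Optional[LocalParams] = None,
                 cfg: Optional[WindowConfig] = None):
        self.clips = list(clips)
        self.p_gt = np.asarray(p_gt, dtype=float)
        if len(self.clips) != self.p_gt.shape[0]:
            raise ValueError("clips and p_gt length mismatch")
        self.plane = plane or FloorPlane.horizontal()
        self.posture_models = dict(posture_models or {})
        self.params = params or LocalParams.reference_preset()
        self.cfg = cfg or WindowConfig()
        self._risk_matrix: Optional[np.ndarray] = None

    def risk_vectors(self, clips: Optional[Sequence[SkeletonClip]] = None
                     ) -> list[RiskVector]:
        """Eight-module risk vectors for the given (default: training) clips."""
        clips = self.clips if clips is None else clips
        return [clip_risk_vector(c, self.plane, self.params,
                                 models=self.posture_models, cfg=self.cfg)
                for c in clips]

    @property
    def exog(self) -> np.ndarray:
        """(n, 8) matrix of training risk vectors (computed once, cached)."""
        if self._risk_matrix is None:
            self._risk_matrix = np.array([rv.p for rv in self.risk_vectors()])
        return self._risk_matrix

    def fit(self, scheme: str = "weighted_mean", T: float = 0.5,
            folds: int = 5, seed: int = 0) -> "FallRiskResults":
        """Fit the fusion stage; ``scheme`` is 'weighted_mean' or 'svm'."""
        R = self.exog
        if scheme == "weighted_mean":
            fusion = fit_weighted_mean_fusion(R, self.p_gt, T=T)
        elif scheme == "svm":
            fusion = train_svm_fusion(R, self.p_gt, T=T, folds=folds, seed=seed)
        else:
            raise ValueError("scheme must be 'weighted_mean' or 'svm'")
        return FallRiskResults(self, fusion)


@dataclass
class FallRiskResults:
    """Fitted fusion stage bound to its parent :class:`FallRiskModel`."""

    model: FallRiskModel
    fusion: FusionModel

    def _matrix(self, clips: Optional[Sequence[SkeletonClip]]) -> np.ndarray:
        if clips is None:
            return self.model.exog
        return np.array([rv.p for rv in self.model.risk_vectors(clips)])

    def predict(self, clips: Optional[Sequence[SkeletonClip]] = None) -> np.ndarray:
        """Overall fused risk (scheme 1) or signed margin (scheme 2) per clip."""
        R = self._matrix(clips)
        return np.array([self.fusion.decision_value(r) for r in R])

    def predict_alarm(self, clips: Optional[Sequence[SkeletonClip]] = None) -> np.ndarray:
        R = self._matrix(clips)
        return np.array([predict_alarm(self.fusion, r) for r in R])

    def evaluate(self, clips: Sequence[SkeletonClip], p_gt
                 ) -> tuple[ConfusionMatrix, Metrics]:
        """Confusion matrix and accuracy/TPR/FPR on a held-out clip set."""
        alarms = self.predict_alarm(clips)
        cm = confusion(np.asarray(p_gt, dtype=float), alarms, T=self.fusion.T)
        return cm, metrics(cm)

    def roc_curve(self, clips: Sequence[SkeletonClip], p_gt):
        """ROC of the weighted-mean overall risk on a held-out set."""
        if self.fusion.scheme != "weighted_mean":
            raise ValueError("ROC sweeps the threshold of the weighted-mean scheme")
        scores = self.predict(clips)
        return roc(np.asarray(p_gt, dtype=float), scores)

    def risk_frame(self, clips: Optional[Sequence[SkeletonClip]] = None) -> pd.DataFrame:
        """Per-clip module risks plus the fused score, as a DataFrame."""
        clips_seq = self.model.clips if clips is None else list(clips)
        rvs = self.model.risk_vectors(clips_seq)
        df = pd.DataFrame([rv.p for rv in rvs], columns=list(MODULES))
        df.insert(0, "clip_id", [rv.clip_id or f"clip{i:03d}"
                                 for i, rv in enumerate(rvs)])
        if self.fusion.scheme == "weighted_mean":
            df["overall"] = [weighted_mean(rv.p, self.fusion.beta) for rv in rvs]
        else:
            df["margin"] = [self.fusion.decision_value(rv.p) for rv in rvs]
        df["alarm"] = [predict_alarm(self.fusion, rv.p) for rv in rvs]
        return df

    def summary(self) -> str:
        """Plain-text summary table of the fitted pipeline."""
        lines = ["Fall-risk fusion results",
                 "=" * 48,
                 f"clips (train):        {len(self.model.clips)}",
                 f"fusion scheme:        {self.fusion.scheme}",
                 f"alarm threshold T:    {self.fusion.T:.2f}"]
        if self.fusion.scheme == "weighted_mean":
            lines += [f"diminishing beta:     {self.fusion.beta:.4f}",
                      f"mean abs fit error:   {self.fusion.fit_error:.4f}"]
        else:
            lines += [f"SVM penalty C:        {self.fusion.C:g}",
                      f"RBF width gamma:      {self.fusion.gamma:g}",
                      f"CV accuracy:          {100 * self.fusion.cv_accuracy:.1f}%"]
        lines.append("-" * 48)
        lines.append("module alphas:")
        for m in MODULES:
            lines.append(f"  {m:<18} {self.model.params[m]:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# end-to-end synthetic experiment
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Everything the end-to-end synthetic experiment measured."""

    params: LocalParams
    calibration_errors: dict[str, float]
    beta: float
    beta_fit_error: float
    svm_C: float
    svm_gamma: float
    wmean_cm: ConfusionMatrix
    wmean_metrics: Metrics
    svm_cm: ConfusionMatrix
    svm_metrics: Metrics
    roc_auc: float
    plane: FloorPlane
    n_train: int
    n_test: int
    extras: dict = field(default_factory=dict)


def run_synthetic_benchmark(seed: int = 0, n_clips: int = 200,
                            n_calibration: int = 20,
                            mix: Optional[dict[str, float]] = None,
                            T: float = 0.5) -> BenchmarkReport:
    """The package's reference experiment, fully synthetic and seeded.

    Steps: (1) RANSAC floor plane from a noisy, partly contaminated floor
    cloud; (2) train the three posture SVMs on generated frame sets;
    (3) calibrate all eight alphas on per-module labelled sweeps;
    (4) generate an ``n_clips`` corpus (half train / half test, stratified),
    score every clip, fit both fusion schemes on the training half and
    evaluate alarms on the held-out half.
    """
    ss = np.random.SeedSequence(seed)
    s_floor, s_post, s_cal, s_data, s_fit = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]

    cloud, _ = generate_floor(tilt_deg=0.0, n_points=400, noise_sd=0.005,
                              outlier_frac=0.2, seed=s_floor)
    plane = fit_floor_ransac(cloud, inlier_tol=0.02, iters=500, seed=s_floor)

    models = {}
    for k, posture in enumerate(("push_up_climb", "pull_up_climb", "sitting")):
        train = posture_training_set(posture, n_per_class=90, seed=s_post + k)
        models[posture] = train_posture(train, kernel_degree=2, posture=posture)

    clips_by_module = {
        m: generate_calibration_set(m, n=n_calibration, seed=s_cal + j)
        for j, m in enumerate(MODULES)}
    params, cal_errors = calibrate_all(clips_by_module, plane, models=models)

    data = generate_dataset(n_clips=n_clips, mix=mix or DEFAULT_MIX, seed=s_data)
    train_clips = [c for c, m in zip(data.clips, data.train_mask) if m]
    test_clips = [c for c, m in zip(data.clips, data.train_mask) if not m]
    y_train = data.p_gt[data.train_mask]
    y_test = data.p_gt[~data.train_mask]

    model = FallRiskModel(train_clips, y_train, plane=plane,
                          posture_models=models, params=params)
    res_w = model.fit("weighted_mean", T=T)
    res_s = model.fit("svm", T=T, seed=s_fit)

    cm_w, met_w = res_w.evaluate(test_clips, y_test)
    cm_s, met_s = res_s.evaluate(test_clips, y_test)
    fpr, tpr = res_w.roc_curve(test_clips, y_test)

    return BenchmarkReport(
        params=params, calibration_errors=cal_errors,
        beta=res_w.fusion.beta, beta_fit_error=res_w.fusion.fit_error,
        svm_C=res_s.fusion.C, svm_gamma=res_s.fusion.gamma,
        wmean_cm=cm_w, wmean_metrics=met_w, svm_cm=cm_s, svm_metrics=met_s,
        roc_auc=auc_trapezoid(fpr, tpr), plane=plane,
        n_train=len(train_clips), n_test=len(test_clips),
        extras={"results_wmean": res_w, "results_svm": res_s,
                "dataset": data},
    )
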