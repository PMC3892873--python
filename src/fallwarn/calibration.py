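"""Local parameter calibration: fitting each module's alpha.

Each module maps its stimulus d to a risk p = 1 - exp(-d^2 / alpha).  Given
expert-labelled pairs (d_i, p_i), taking logs linearizes the model into the
over-determined system

    [-ln(1 - p_i)] * alpha = [d_i^2],

whose least-squares solution is the closed form

    alpha = sum(a_i * b_i) / sum(a_i^2),   a_i = -ln(1 - p_i),  b_i = d_i^2.

Rows with p_i = 0 have a_i = 0 and drop out of both sums; p_i >= 1 is
rejected (the log term diverges).  The reported fit error is the mean
absolute deviation between the refitted sigmoid and the labels.

Clip-level calibration aggregates the raw per-frame stimulus by its temporal
mean before fitting (keeping the linearized system exact in the aggregated
stimulus), then solves per module.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .floor import FloorPlane
from .posture import PostureModel
from .risks import (MODULES, LocalParams, WindowConfig, foot_altitude_distance,
                    ground_speed, head_altitude_excess, height_variance,
                    lean_angle, sway_distance)
from .skeleton import SkeletonClip, clip_feature_matrix


@dataclass
class CalibrationSet:
    """Stimulus/ground-truth pairs for one module: d_i >= 0, p_i in [0, 1)."""

    d: np.ndarray
    p: np.ndarray
    module: Optional[str] = None

    def __post_init__(self) -> None:
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if self.d.shape != self.p.shape:
            raise ValueError("d and p must have equal length")
        if self.d.size < 1:
            raise ValueError("need at least one pair")
        if np.any(self.p < 0) or np.any(self.p >= 1):
            raise ValueError("ground-truth risks must lie in [0, 1) "
                             "(p = 1 makes the log term singular)")


def fit_alpha(cal: CalibrationSet) -> tuple[float, float]:
    """Closed-form least-squares alpha and its mean absolute fit error."""
    a = -np.log1p(-cal.p)
    b = np.square(cal.d)
    denom = float(np.sum(a * a))
    if denom == 0.0:
        raise ValueError("uninformative calibration set: all p_i are zero")
    alpha = float(np.sum(a * b)) / denom
    if alpha <= 0:
        raise ValueError("calibration produced a non-positive alpha "
                         "(stimuli inconsistent with labels)")
    fitted = -np.expm1(-b / alpha)
    fit_error = float(np.mean(np.abs(fitted - cal.p)))
    return alpha, fit_error


def clip_stimulus(module: str, clip: SkeletonClip, plane: FloorPlane,
                  models: Optional[Mapping[str, PostureModel]] = None,
                  cfg: Optional[WindowConfig] = None) -> float:
    """Clip-level mean of a module's raw per-frame stimulus.

    Climb modules use the positive part of the SVM confidence distance; the
    jump module uses the per-frame windowed standard deviation (so that the
    squared stimulus is the variance of the sigmoid); sway/lean/altitude use
    their per-frame distances, ignoring frames where the module is
    unavailable.  Head altitude averages the positive part of the excess on
    foot-occluded frames (or all frames if the feet are never occluded).
    """
    cfg = cfg or WindowConfig()
    ff = clip.forward_filled()
    models = models or {}
    if module in ("push_up_climb", "pull_up_climb"):
        if module not in models:
            raise ValueError(f"no posture model for {module}")
        d = models[module].decision_distances(clip_feature_matrix(ff))
        return float(np.mean(np.maximum(d, 0.0)))
    if module == "run":
        return float(np.mean(ground_speed(ff, plane, cfg)))
    if module == "jump":
        return float(np.mean(np.sqrt(height_variance(ff, plane, cfg))))
    if module == "sway":
        d = sway_distance(ff, plane)
        return float(np.nanmean(d)) if np.any(~np.isnan(d)) else 0.0
    if module == "lean":
        theta = lean_angle(ff, plane)
        return float(np.nanmean(theta)) if np.any(~np.isnan(theta)) else 0.0
    if module == "foot_altitude":
        d = foot_altitude_distance(ff, plane)
        return float(np.nanmean(d)) if np.any(~np.isnan(d)) else 0.0
    if module == "head_altitude":
        d = head_altitude_excess(ff, plane)
        from .skeleton import JointName
        occluded = ~(clip.tracked[:, JointName.FOOT_LEFT]
                     & clip.tracked[:, JointName.FOOT_RIGHT])
        sel = d[occluded] if occluded.any() else d
        sel = sel[~np.isnan(sel)]
        return float(np.mean(np.maximum(sel, 0.0))) if sel.size else 0.0
    raise KeyError(f"unknown module: {module}")


def calibrate_all(
    clips_by_module: Mapping[str, Sequence[tuple[SkeletonClip, float]]],
    plane: FloorPlane,
    models: Optional[Mapping[str, PostureModel]] = None,
    cfg: Optional[WindowConfig] = None,
    preset: Optional[LocalParams] = None,
) -> tuple[LocalParams, dict[str, float]]:
    """Fit every module's alpha from labelled clips.

    ``clips_by_module`` maps module names to (clip, p_gt) pairs.  Modules
    without data keep the preset value (a warning is emitted) and report a
    NaN fit error.
    """
    preset = preset or LocalParams.reference_preset()
    params = replace(preset)
    errors: dict[str, float] = {}
    for module in MODULES:
        pairs = clips_by_module.get(module)
        if not pairs:
            warnings.warn(f"no calibration clips for module {module}; "
                          "keeping preset alpha", stacklevel=2)
            errors[module] = float("nan")
            continue
        d = np.array([clip_stimulus(module, clip, plane, models, cfg)
                      for clip, _ in pairs])
        p = np.array([p_gt for _, p_gt in pairs])
        alpha, err = fit_alpha(CalibrationSet(d, p, module=module))
        params = replace(params, **{module: alpha})
        errors[module] = err
    return params, errors


def save_params(params: LocalParams, path: Union[str, Path],
                errors: Optional[Mapping[str, float]] = None) -> None:
    payload: dict = {"alpha": params.as_dict()}
    if errors is not None:
        payload["fit_error"] = dict(errors)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_params(path: Union[str, Path]) -> LocalParams:
    payload = json.loads(Path(path).read_text())
    return LocalParams(**payload["alpha"])
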