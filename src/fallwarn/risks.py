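"""The eight per-module fall-risk computations on a skeleton clip.

Every module turns a physical stimulus s (a speed, a variance, a distance, an
angle) into a per-frame fall risk through the same saturating map

    p = 1 - exp(-s^2 / alpha)

with a module-local scale parameter alpha > 0.  The eight modules, grouped by
criterion:

========  ==================  ===========================================
criterion module              stimulus
========  ==================  ===========================================
posture   push_up_climb       SVM confidence distance (positive side)
posture   pull_up_climb       SVM confidence distance (positive side)
motion    run                 ground-projected centroid speed (m/s)
motion    jump                windowed variance of centroid altitude (m^2)
balance   sway                centroid distance to base-of-support line (m)
balance   lean                spine angle against the floor normal (rad)
altitude  foot_altitude       foot-midpoint altitude above the floor (m)
altitude  head_altitude       head altitude minus body height, clamped (m)
========  ==================  ===========================================

Gating: a detected sitting posture disables sway and foot altitude; head
altitude engages only on frames where the feet are occluded; a module that is
disabled or cannot locate its joints contributes risk zero.  Clip-level
values are the temporal means of the per-frame risks.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Optional

import numpy as np

from .floor import FloorPlane, base_of_support_distance, ground_project, point_plane_distance
from .posture import PostureModel, risk_from_distance
from .skeleton import (JointName, SkeletonClip, clip_centroids,
                       clip_feature_matrix, clip_heights, clip_spine_vectors)

#: Canonical module order of the 8-vector.
MODULES: tuple[str, ...] = (
    "push_up_climb", "pull_up_climb", "run", "jump",
    "sway", "lean", "foot_altitude", "head_altitude",
)


@dataclass
class LocalParams:
    """The per-module sigmoid scales alpha_1..alpha_8 (all > 0)."""

    push_up_climb: float = 0.167
    pull_up_climb: float = 0.168
    run: float = 0.009
    jump: float = 0.017
    sway: float = 0.008
    lean: float = 0.115
    foot_altitude: float = 0.217
    head_altitude: float = 0.214

    def __post_init__(self) -> None:
        for name in MODULES:
            if getattr(self, name) <= 0:
                raise ValueError(f"alpha for {name} must be positive")

    @classmethod
    def reference_preset(cls) -> "LocalParams":
        """The published reference alpha values (units tied to the original
        sensor setup; local calibration is the normative source)."""
        return cls()

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def __getitem__(self, module: str) -> float:
        if module not in MODULES:
            raise KeyError(module)
        return getattr(self, module)


@dataclass
class WindowConfig:
    """Temporal windows: centered velocity smoothing and the trailing
    variance window for the jump module (frames; both >= 2)."""

    velocity_smoothing: int = 5
    variance_window: int = 30

    def __post_init__(self) -> None:
        if self.velocity_smoothing < 2 or self.variance_window < 2:
            raise ValueError("windows must be >= 2 frames")


@dataclass
class RiskVector:
    """The eight clip-level risks plus per-module enabled flags."""

    p: np.ndarray
    enabled: np.ndarray
    clip_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.enabled = np.asarray(self.enabled, dtype=bool)
        if self.p.shape != (len(MODULES),) or self.enabled.shape != (len(MODULES),):
            raise ValueError(f"expected {len(MODULES)} modules")
        if np.any(self.p[~self.enabled] != 0.0):
            raise ValueError("disabled modules must carry zero risk")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("risks must lie in [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {m: float(v) for m, v in zip(MODULES, self.p)}


def _sigmoid_risk(stimulus_sq: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return -np.expm1(-stimulus_sq / alpha)


def _centered_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with shrinking edge windows."""
    half = window // 2
    T = x.shape[0]
    out = np.empty_like(x, dtype=float)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        out[t] = x[lo:hi].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# stimulus extraction (shared with calibration)
# ---------------------------------------------------------------------------

def ground_speed(clip: SkeletonClip, plane: FloorPlane,
                 cfg: Optional[WindowConfig] = None) -> np.ndarray:
    """Per-frame smoothed speed of the ground-projected centroid (m/s)."""
    cfg = cfg or WindowConfig()
    if clip.n_frames < 2:
        raise ValueError("need at least 2 frames for a velocity")
    pc = ground_project(clip_centroids(clip), plane)
    vel = np.gradient(pc, axis=0) * clip.frame_rate
    vel = _centered_mean(vel, cfg.velocity_smoothing)
    return np.linalg.norm(vel, axis=1)


def height_variance(clip: SkeletonClip, plane: FloorPlane,
                    cfg: Optional[WindowConfig] = None,
                    strict: bool = True) -> np.ndarray:
    """Per-frame trailing-window variance of the centroid's altitude (m^2).

    Frames earlier than one full window use the available (expanding) prefix;
    a clip shorter than the window is evaluated over the whole clip.
    """
    cfg = cfg or WindowConfig()
    h = point_plane_distance(clip_centroids(clip), plane, strict=strict)
    T = h.shape[0]
    w = cfg.variance_window
    out = np.empty(T)
    for t in range(T):
        lo = max(0, t - w + 1)
        out[t] = h[lo:t + 1].var() if t - lo >= 1 else 0.0
    return out


def sway_distance(clip: SkeletonClip, plane: FloorPlane) -> np.ndarray:
    """Per-frame distance of the projected centroid to the foot line (m).

    Frames with an untracked foot yield NaN (module unavailable there).
    """
    pc = ground_project(clip_centroids(clip), plane)
    fl = ground_project(clip.positions[:, JointName.FOOT_LEFT], plane)
    fr = ground_project(clip.positions[:, JointName.FOOT_RIGHT], plane)
    feet_ok = clip.tracked[:, JointName.FOOT_LEFT] & clip.tracked[:, JointName.FOOT_RIGHT]
    out = np.full(clip.n_frames, np.nan)
    for t in np.flatnonzero(feet_ok):
        out[t] = base_of_support_distance(pc[t], fl[t], fr[t])
    return out


def lean_angle(clip: SkeletonClip, plane: FloorPlane) -> np.ndarray:
    """Per-frame angle (rad) between the spine vector and the floor normal.

    Zero-length spine vectors yield NaN.
    """
    spine = clip_spine_vectors(clip)
    norms = np.linalg.norm(spine, axis=1)
    cosang = np.full(clip.n_frames, np.nan)
    ok = norms > 1e-9
    cosang[ok] = np.clip(spine[ok] @ plane.normal / norms[ok], -1.0, 1.0)
    return np.arccos(cosang)


def foot_altitude_distance(clip: SkeletonClip, plane: FloorPlane,
                           strict: bool = True) -> np.ndarray:
    """Per-frame altitude of the feet midpoint above the floor (m);
    NaN where a foot is untracked."""
    pf = 0.5 * (clip.positions[:, JointName.FOOT_LEFT]
                + clip.positions[:, JointName.FOOT_RIGHT])
    d = point_plane_distance(pf, plane, strict=strict)
    feet_ok = clip.tracked[:, JointName.FOOT_LEFT] & clip.tracked[:, JointName.FOOT_RIGHT]
    return np.where(feet_ok, d, np.nan)


def head_altitude_excess(clip: SkeletonClip, plane: FloorPlane,
                         strict: bool = True) -> np.ndarray:
    """Per-frame signed head-altitude excess d = alt(HEAD) - H (m).

    Positive only when the head sits higher above the floor than one body
    height, i.e. the (unseen) feet must be off the ground.  NaN where the
    head is untracked or H is not computable.
    """
    alt = point_plane_distance(clip.positions[:, JointName.HEAD], plane, strict=strict)
    H = clip_heights(clip)
    ok = clip.tracked[:, JointName.HEAD]
    return np.where(ok, alt - H, np.nan)


# ---------------------------------------------------------------------------
# per-frame module risks
# ---------------------------------------------------------------------------

def risk_run(clip: SkeletonClip, plane: FloorPlane, alpha3: float,
             cfg: Optional[WindowConfig] = None) -> np.ndarray:
    """Rush-running risk p = 1 - exp(-||V_c||^2 / alpha3) per frame."""
    speed = ground_speed(clip, plane, cfg)
    return _sigmoid_risk(np.square(speed), alpha3)


def risk_jump(clip: SkeletonClip, plane: FloorPlane, alpha4: float,
              cfg: Optional[WindowConfig] = None) -> np.ndarray:
    """High-jumping risk p = 1 - exp(-sigma^2 / alpha4) per frame."""
    var = height_variance(clip, plane, cfg)
    return _sigmoid_risk(var, alpha4)


def risk_sway(clip: SkeletonClip, plane: FloorPlane, alpha5: float,
              seated: Optional[np.ndarray] = None) -> np.ndarray:
    """Body-sway risk p = 1 - exp(-d(P_c, L)^2 / alpha5) per frame.

    Seated frames and frames with untracked feet contribute zero.
    """
    d = sway_distance(clip, plane)
    risk = np.where(np.isnan(d), 0.0, _sigmoid_risk(np.square(np.nan_to_num(d)), alpha5))
    if seated is not None:
        risk = np.where(np.asarray(seated, dtype=bool), 0.0, risk)
    return risk


def risk_lean(clip: SkeletonClip, plane: FloorPlane, alpha6: float) -> np.ndarray:
    """Body-lean risk p = 1 - exp(-theta_h^2 / alpha6) per frame."""
    theta = lean_angle(clip, plane)
    return np.where(np.isnan(theta), 0.0,
                    _sigmoid_risk(np.square(np.nan_to_num(theta)), alpha6))


def risk_foot_altitude(clip: SkeletonClip, plane: FloorPlane, alpha7: float,
                       seated: Optional[np.ndarray] = None,
                       strict: bool = True) -> np.ndarray:
    """Foot-altitude risk p = 1 - exp(-d(P_f, F)^2 / alpha7) per frame."""
    d = foot_altitude_distance(clip, plane, strict=strict)
    risk = np.where(np.isnan(d), 0.0, _sigmoid_risk(np.square(np.nan_to_num(d)), alpha7))
    if seated is not None:
        risk = np.where(np.asarray(seated, dtype=bool), 0.0, risk)
    return risk


def risk_head_altitude(clip: SkeletonClip, plane: FloorPlane, alpha8: float,
                       strict: bool = True) -> np.ndarray:
    """Head-altitude risk p = 1 - exp(-d^2 / alpha8) where d > 0, else 0."""
    d = head_altitude_excess(clip, plane, strict=strict)
    d = np.nan_to_num(d, nan=0.0)
    return np.where(d > 0, _sigmoid_risk(np.square(d), alpha8), 0.0)


def seated_mask_from_model(clip: SkeletonClip, sitting_model: PostureModel) -> np.ndarray:
    """Per-frame sitting detection over a (forward-filled) clip."""
    X = clip_feature_matrix(clip)
    return sitting_model.decision_distances(X) > 0


def clip_risk_vector(clip: SkeletonClip, plane: FloorPlane, params: LocalParams,
                     models: Optional[Mapping[str, PostureModel]] = None,
                     cfg: Optional[WindowConfig] = None,
                     seated_mask: Optional[np.ndarray] = None,
                     clip_id: Optional[str] = None) -> RiskVector:
    """Run all eight modules on a clip and take temporal means.

    ``models`` may hold posture SVMs under keys ``push_up_climb``,
    ``pull_up_climb`` and ``sitting``; climb modules without a model are
    disabled (zero).  ``seated_mask`` (e.g. from occlusion-mode switching) is
    OR-ed with per-frame sitting detection to gate sway and foot altitude.
    Head altitude engages only on frames whose feet are untracked.
    """
    cfg = cfg or WindowConfig()
    models = models or {}
    ff = clip.forward_filled()
    T = clip.n_frames

    seated = np.zeros(T, dtype=bool)
    if seated_mask is not None:
        seated |= np.asarray(seated_mask, dtype=bool)
    if "sitting" in models:
        seated |= seated_mask_from_model(ff, models["sitting"])

    feet_occluded = ~(clip.tracked[:, JointName.FOOT_LEFT]
                      & clip.tracked[:, JointName.FOOT_RIGHT])

    p = np.zeros(len(MODULES))
    enabled = np.ones(len(MODULES), dtype=bool)

    X = clip_feature_matrix(ff)
    for i, key in enumerate(("push_up_climb", "pull_up_climb")):
        if key in models:
            d = models[key].decision_distances(X)
            p[i] = float(np.mean(risk_from_distance(d, params[key])))
        else:
            enabled[i] = False

    p[2] = float(np.mean(risk_run(ff, plane, params.run, cfg)))
    p[3] = float(np.mean(risk_jump(ff, plane, params.jump, cfg)))
    p[4] = float(np.mean(risk_sway(ff, plane, params.sway, seated)))
    p[5] = float(np.mean(risk_lean(ff, plane, params.lean)))
    p[6] = float(np.mean(risk_foot_altitude(ff, plane, params.foot_altitude, seated)))
    if seated.all():
        enabled[4] = enabled[6] = False
        p[4] = p[6] = 0.0

    if feet_occluded.any():
        head = risk_head_altitude(ff, plane, params.head_altitude)
        p[7] = float(np.mean(np.where(feet_occluded, head, 0.0)))
    else:
        enabled[7] = False

    return RiskVector(p, enabled, clip_id=clip_id or clip.clip_id)
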