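"""Parametric generator of labelled toddler-behavior skeleton clips.

The generator emulates the kind of corpus a depth camera would record in a
living room: 3-second 20-joint skeleton clips of ten everyday toddler
behaviors (five safe, five fall-prone), tilted noisy floor point clouds,
lower-body occlusion episodes with their depth-profile summaries, and
expert-questionnaire-style ground-truth risk labels on the 0, 0.1, ..., 1
scale.

Kinematics are deliberately simple but physically scaled: a ~0.84 m standing
toddler template animated by a small set of drivers -- gait translation and
limb swing, whole-body vertical oscillation (jumping), anterior-posterior
torso sway relative to the feet, spine lean about the hips, static climbing
poses (push-up and pull-up variants) and whole-body elevation (furniture) --
plus isotropic Gaussian joint jitter.  Each behavior's ``intensity`` in
[0, 1] monotonically drives its dominant criterion.

The expert labeller is replaced by an explicit deterministic rule
(:func:`label_for`): a saturating-exponential response of the behavior's
dominant nominal driver, quantized to the 0.1 questionnaire grid, with scale
constants fixed so the five safe behaviors sit below 0.5 and the five
fall-prone ones above at default intensity.  The substitution is recorded in
clip metadata (``behavior`` tags) and discussed in the package docs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .occlusion import DepthProfile
from .posture import TrainingSet
from .skeleton import JointName, N_JOINTS, SkeletonClip, clip_feature_matrix

SAFE_BEHAVIORS: tuple[str, ...] = (
    "sitting", "standing", "walking", "jumping_rope", "dancing")
RISKY_BEHAVIORS: tuple[str, ...] = (
    "rush_running", "high_jumping", "tumbling", "climbing", "standing_on_furniture")
BEHAVIORS: tuple[str, ...] = SAFE_BEHAVIORS + RISKY_BEHAVIORS

# ---------------------------------------------------------------------------
# plausibility constants (single source of truth for the study conditions)
# ---------------------------------------------------------------------------

#: top running speed (m/s) at intensity 1
V_MAX = 2.5
#: top walking speed (m/s) at intensity 1 -- walking is a gentler gait
V_WALK = 1.2
#: top whole-body jump amplitude (m)
H_MAX = 0.35
#: rope-skipping jump amplitude cap (m)
H_ROPE = 0.12
#: torso sway amplitude caps (m)
SWAY_MAX = 0.4
SWAY_DANCE = 0.15
#: maximum spine lean (rad); 60 degrees
LEAN_MAX = math.radians(60.0)
LEAN_DANCE = 0.3
#: furniture elevation (m) at intensity 1
FURNITURE_H = 0.6
#: climbing elevation ramp (m) at intensity 1
CLIMB_H = 0.3
#: default per-joint Gaussian jitter (m), Kinect-like
NOISE_SD = 0.002

#: Expert-response scales of the label rule: the squared-stimulus scale at
#: which the questionnaire answer saturates, per dominant criterion driver.
LABEL_SCALES: dict[str, float] = {
    "run": 1.13,        # (m/s)^2 on nominal gait speed
    "jump": 0.0221,     # m^2 on nominal jump amplitude
    "sway": 0.0289,     # m^2 on nominal sway amplitude
    "lean": 0.30,       # rad^2 on nominal lean angle
    "altitude": 0.0649, # m^2 on nominal elevation
}


def _label_sigmoid(stimulus: float, scale_key: str) -> float:
    return -math.expm1(-stimulus ** 2 / LABEL_SCALES[scale_key])


def _quantize(p: float) -> float:
    """Snap to the 0.1 questionnaire grid, capped to [0, 0.9] for singles."""
    return min(0.9, max(0.0, math.floor(p * 10.0 + 0.5) / 10.0))


def label_for(behavior: str, intensity: float) -> float:
    """Expert-stand-in ground-truth risk for a single behavior.

    Deterministic questionnaire emulation on the 0.1 grid; see the module
    docstring for the rationale.
    """
    i = float(intensity)
    if behavior == "sitting" or behavior == "standing":
        return 0.1
    if behavior == "walking":
        return _quantize(_label_sigmoid(V_WALK * i, "run"))
    if behavior == "jumping_rope":
        return _quantize(_label_sigmoid(H_ROPE * i, "jump"))
    if behavior == "dancing":
        return _quantize(max(_label_sigmoid(SWAY_DANCE * i, "sway"),
                             _label_sigmoid(LEAN_DANCE * i, "lean")))
    if behavior == "rush_running":
        return _quantize(_label_sigmoid(V_MAX * i, "run"))
    if behavior == "high_jumping":
        return _quantize(_label_sigmoid(H_MAX * i, "jump"))
    if behavior == "tumbling":
        return _quantize(max(_label_sigmoid(SWAY_MAX * i, "sway"),
                             _label_sigmoid(LEAN_MAX * i, "lean")))
    if behavior == "climbing":
        return _quantize(0.55 + 0.35 * i)
    if behavior == "standing_on_furniture":
        return _quantize(_label_sigmoid(FURNITURE_H * i, "altitude"))
    raise ValueError(f"unknown behavior: {behavior}")


def combined_label(primary: str, secondary: str, intensity: float) -> float:
    """Combined-behavior rule: max of the component labels plus 0.1, capped."""
    return min(1.0, max(label_for(primary, intensity),
                        label_for(secondary, intensity)) + 0.1)


@dataclass
class BehaviorSpec:
    """One clip's generation recipe."""

    behavior: str
    intensity: float = 0.5
    duration: float = 3.0
    seed: int = 0
    noise_sd: float = NOISE_SD
    occluded_from: Optional[int] = None      # frame index; None = no occlusion
    climb_variant: Optional[str] = None      # "push" | "pull" (default: by seed)
    combined_with: Optional[str] = None      # secondary behavior for combos

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior: {self.behavior}")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def p_gt(self) -> float:
        if self.combined_with is not None:
            return combined_label(self.behavior, self.combined_with, self.intensity)
        return label_for(self.behavior, self.intensity)


# ---------------------------------------------------------------------------
# skeleton templates (toddler anthropometry, metres; x lateral, y up, z depth)
# ---------------------------------------------------------------------------

def _mirror(template: dict, left: JointName, right: JointName) -> None:
    x, y, z = template[left]
    template[right] = (-x, y, z)


def _standing_template() -> np.ndarray:
    t: dict[JointName, tuple[float, float, float]] = {
        JointName.HIP_CENTER: (0.0, 0.42, 0.0),
        JointName.SPINE: (0.0, 0.55, 0.0),
        JointName.SHOULDER_CENTER: (0.0, 0.68, 0.0),
        JointName.HEAD: (0.0, 0.80, 0.0),
        JointName.SHOULDER_LEFT: (-0.10, 0.66, 0.0),
        JointName.ELBOW_LEFT: (-0.13, 0.52, 0.0),
        JointName.WRIST_LEFT: (-0.14, 0.42, 0.02),
        JointName.HAND_LEFT: (-0.14, 0.38, 0.03),
        JointName.HIP_LEFT: (-0.07, 0.40, 0.0),
        JointName.KNEE_LEFT: (-0.08, 0.22, 0.0),
        JointName.ANKLE_LEFT: (-0.08, 0.04, 0.0),
        JointName.FOOT_LEFT: (-0.08, 0.01, 0.02),
    }
    for l, r in ((JointName.SHOULDER_LEFT, JointName.SHOULDER_RIGHT),
                 (JointName.ELBOW_LEFT, JointName.ELBOW_RIGHT),
                 (JointName.WRIST_LEFT, JointName.WRIST_RIGHT),
                 (JointName.HAND_LEFT, JointName.HAND_RIGHT),
                 (JointName.HIP_LEFT, JointName.HIP_RIGHT),
                 (JointName.KNEE_LEFT, JointName.KNEE_RIGHT),
                 (JointName.ANKLE_LEFT, JointName.ANKLE_RIGHT),
                 (JointName.FOOT_LEFT, JointName.FOOT_RIGHT)):
        _mirror(t, l, r)
    return np.array([t[j] for j in JointName], dtype=float)


def _seated_template() -> np.ndarray:
    t: dict[JointName, tuple[float, float, float]] = {
        JointName.HIP_CENTER: (0.0, 0.24, 0.0),
        JointName.SPINE: (0.0, 0.37, 0.02),
        JointName.SHOULDER_CENTER: (0.0, 0.50, 0.04),
        JointName.HEAD: (0.0, 0.62, 0.05),
        JointName.SHOULDER_LEFT: (-0.10, 0.48, 0.04),
        JointName.ELBOW_LEFT: (-0.12, 0.36, 0.06),
        JointName.WRIST_LEFT: (-0.13, 0.28, 0.10),
        JointName.HAND_LEFT: (-0.13, 0.25, 0.12),
        JointName.HIP_LEFT: (-0.07, 0.22, 0.0),
        JointName.KNEE_LEFT: (-0.08, 0.22, 0.18),
        JointName.ANKLE_LEFT: (-0.08, 0.04, 0.22),
        JointName.FOOT_LEFT: (-0.08, 0.01, 0.26),
    }
    for l, r in ((JointName.SHOULDER_LEFT, JointName.SHOULDER_RIGHT),
                 (JointName.ELBOW_LEFT, JointName.ELBOW_RIGHT),
                 (JointName.WRIST_LEFT, JointName.WRIST_RIGHT),
                 (JointName.HAND_LEFT, JointName.HAND_RIGHT),
                 (JointName.HIP_LEFT, JointName.HIP_RIGHT),
                 (JointName.KNEE_LEFT, JointName.KNEE_RIGHT),
                 (JointName.ANKLE_LEFT, JointName.ANKLE_RIGHT),
                 (JointName.FOOT_LEFT, JointName.FOOT_RIGHT)):
        _mirror(t, l, r)
    return np.array([t[j] for j in JointName], dtype=float)


_STANDING = _standing_template()
_SEATED = _seated_template()

_UPPER_JOINTS = np.arange(0, 12)    # hip center .. right hand
_LOWER_JOINTS = np.arange(12, 20)   # hips .. feet
_TORSO_ROT = np.arange(1, 12)       # joints pitched about the hip center

_LEFT_LEG = (JointName.KNEE_LEFT, JointName.ANKLE_LEFT, JointName.FOOT_LEFT)
_RIGHT_LEG = (JointName.KNEE_RIGHT, JointName.ANKLE_RIGHT, JointName.FOOT_RIGHT)
_LEFT_ARM = (JointName.ELBOW_LEFT, JointName.WRIST_LEFT, JointName.HAND_LEFT)
_RIGHT_ARM = (JointName.ELBOW_RIGHT, JointName.WRIST_RIGHT, JointName.HAND_RIGHT)


def _climb_template(variant: str, intensity: float) -> np.ndarray:
    """Static climbing pose: arms committed to a support, scaled by intensity."""
    pose = _STANDING.copy()
    i = intensity
    if variant == "push":
        # hands pushing down on a low surface ahead, one leg raised onto it
        for j, dy, dz in ((JointName.ELBOW_LEFT, 0.10, 0.10),
                          (JointName.WRIST_LEFT, 0.30, 0.18),
                          (JointName.HAND_LEFT, 0.35, 0.22),
                          (JointName.ELBOW_RIGHT, 0.10, 0.10),
                          (JointName.WRIST_RIGHT, 0.30, 0.18),
                          (JointName.HAND_RIGHT, 0.35, 0.22),
                          (JointName.KNEE_RIGHT, 0.25, 0.12),
                          (JointName.ANKLE_RIGHT, 0.25, 0.10),
                          (JointName.FOOT_RIGHT, 0.25, 0.14),
                          (JointName.SPINE, 0.0, 0.04),
                          (JointName.SHOULDER_CENTER, 0.0, 0.07),
                          (JointName.HEAD, 0.0, 0.10)):
            pose[j] += (0.0, dy * i, dz * i)
    elif variant == "pull":
        # arms stretched overhead, gripping a high support
        for j, dy, dz in ((JointName.ELBOW_LEFT, 0.30, 0.04),
                          (JointName.WRIST_LEFT, 0.55, 0.06),
                          (JointName.HAND_LEFT, 0.62, 0.08),
                          (JointName.ELBOW_RIGHT, 0.30, 0.04),
                          (JointName.WRIST_RIGHT, 0.55, 0.06),
                          (JointName.HAND_RIGHT, 0.62, 0.08),
                          (JointName.KNEE_LEFT, 0.10, 0.04),
                          (JointName.ANKLE_LEFT, 0.12, 0.02),
                          (JointName.FOOT_LEFT, 0.12, 0.04)):
            pose[j] += (0.0, dy * i, dz * i)
    else:
        raise ValueError("climb variant must be 'push' or 'pull'")
    return pose


@dataclass
class _Drivers:
    """Internal kinematic recipe assembled per behavior."""

    template: np.ndarray = field(default_factory=lambda: _STANDING.copy())
    speed: float = 0.0              # gait translation (m/s, along z)
    jump_amp: float = 0.0           # whole-body vertical oscillation (m)
    jump_freq: float = 1.5
    sway_amp: float = 0.0           # torso anterior-posterior offset (m)
    sway_freq: float = 0.7
    lean_amp: float = 0.0           # oscillating lean (rad)
    lean_freq: float = 0.5
    lean_static: float = 0.0        # constant lean (rad)
    elevation: float = 0.0          # whole-body offset (m)
    elevation_ramp: float = 0.0     # linear 0 -> ramp over the clip (m)

    def merge(self, other: "_Drivers") -> "_Drivers":
        return _Drivers(
            template=self.template,
            speed=self.speed + other.speed,
            jump_amp=self.jump_amp + other.jump_amp,
            jump_freq=self.jump_freq,
            sway_amp=self.sway_amp + other.sway_amp,
            sway_freq=self.sway_freq if self.sway_amp else other.sway_freq,
            lean_amp=self.lean_amp + other.lean_amp,
            lean_freq=self.lean_freq if self.lean_amp else other.lean_freq,
            lean_static=self.lean_static + other.lean_static,
            elevation=self.elevation + other.elevation,
            elevation_ramp=self.elevation_ramp + other.elevation_ramp,
        )


def _behavior_drivers(behavior: str, intensity: float,
                      climb_variant: str) -> _Drivers:
    i = intensity
    if behavior == "sitting":
        return _Drivers(template=_SEATED.copy())
    if behavior == "standing":
        return _Drivers()
    if behavior == "walking":
        return _Drivers(speed=V_WALK * i)
    if behavior == "jumping_rope":
        return _Drivers(jump_amp=H_ROPE * i, jump_freq=2.0)
    if behavior == "dancing":
        return _Drivers(sway_amp=SWAY_DANCE * i, sway_freq=0.9,
                        lean_amp=LEAN_DANCE * i, lean_freq=0.6)
    if behavior == "rush_running":
        return _Drivers(speed=V_MAX * i)
    if behavior == "high_jumping":
        return _Drivers(jump_amp=H_MAX * i, jump_freq=1.5)
    if behavior == "tumbling":
        return _Drivers(sway_amp=SWAY_MAX * i, sway_freq=0.7,
                        lean_amp=LEAN_MAX * i, lean_freq=0.5)
    if behavior == "climbing":
        return _Drivers(template=_climb_template(climb_variant, i),
                        elevation_ramp=CLIMB_H * i)
    if behavior == "standing_on_furniture":
        return _Drivers(elevation=FURNITURE_H * i)
    raise ValueError(f"unknown behavior: {behavior}")


def _apply_gait(pos: np.ndarray, t: np.ndarray, speed: float) -> None:
    """Translate along z at ``speed`` with antiphase limb swing."""
    pos[:, :, 2] += (speed * t)[:, None]
    if speed <= 0:
        return
    freq = max(1.0, 1.2 * speed)
    phase = np.sin(2.0 * np.pi * freq * t)
    lift = np.maximum(0.0, phase)
    stride = min(0.25, 0.06 + 0.06 * speed)
    for j in _LEFT_LEG:
        pos[:, j, 2] += stride * phase
        pos[:, j, 1] += 0.03 * lift
    for j in _RIGHT_LEG:
        pos[:, j, 2] -= stride * phase
        pos[:, j, 1] += 0.03 * np.maximum(0.0, -phase)
    arm = 0.05 * min(1.0, speed)
    for j in _LEFT_ARM:
        pos[:, j, 2] -= arm * phase
    for j in _RIGHT_ARM:
        pos[:, j, 2] += arm * phase


def _build_positions(drv: _Drivers, n_frames: int, frame_rate: float) -> np.ndarray:
    t = np.arange(n_frames) / frame_rate
    pos = np.tile(drv.template, (n_frames, 1, 1))
    _apply_gait(pos, t, drv.speed)
    if drv.sway_amp:
        sway = drv.sway_amp * np.sin(2.0 * np.pi * drv.sway_freq * t)
        pos[:, _UPPER_JOINTS, 2] += sway[:, None]
    theta = np.full(n_frames, drv.lean_static)
    if drv.lean_amp:
        theta = theta + drv.lean_amp * np.sin(2.0 * np.pi * drv.lean_freq * t)
    if np.any(theta != 0.0):
        hip = pos[:, JointName.HIP_CENTER, :][:, None, :]
        rel = pos[:, _TORSO_ROT, :] - hip
        c, s = np.cos(theta)[:, None], np.sin(theta)[:, None]
        y, z = rel[:, :, 1].copy(), rel[:, :, 2].copy()
        rel[:, :, 1] = c * y - s * z
        rel[:, :, 2] = s * y + c * z
        pos[:, _TORSO_ROT, :] = hip + rel
    if drv.jump_amp:
        bounce = 0.5 * drv.jump_amp * (1.0 - np.cos(2.0 * np.pi * drv.jump_freq * t))
        pos[:, :, 1] += bounce[:, None]
    if drv.elevation:
        pos[:, :, 1] += drv.elevation
    if drv.elevation_ramp:
        pos[:, :, 1] += (drv.elevation_ramp * np.clip(t / t[-1] if t[-1] > 0 else t, 0, 1))[:, None]
    return pos


def generate_clip(spec: BehaviorSpec,
                  frame_rate: float = 30.0) -> tuple[SkeletonClip, DepthProfile]:
    """Generate one labelled skeleton clip and its depth-profile summary.

    Deterministic in ``spec.seed``: the same spec yields a bit-identical
    clip.  The clip carries the label-rule ground truth in ``p_gt`` and a
    behavior tag recording the (possibly combined) recipe.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = max(2, int(round(spec.duration * frame_rate)))
    variant = spec.climb_variant or ("push" if spec.seed % 2 == 0 else "pull")

    drv = _behavior_drivers(spec.behavior, spec.intensity, variant)
    if spec.combined_with is not None:
        drv = drv.merge(_behavior_drivers(spec.combined_with, spec.intensity, variant))

    pos = _build_positions(drv, n_frames, frame_rate)
    # random placement in the camera frustum
    x0 = rng.uniform(-0.5, 0.5)
    z0 = rng.uniform(2.0, 3.0)
    pos[:, :, 0] += x0
    pos[:, :, 2] += z0
    pos += rng.normal(0.0, spec.noise_sd, size=pos.shape)

    tracked = np.ones((n_frames, N_JOINTS), dtype=bool)
    upper_depth = pos[:, _UPPER_JOINTS, 2].mean(axis=1) + rng.normal(0, 0.01, n_frames)
    lower_depth = pos[:, _LOWER_JOINTS, 2].mean(axis=1) + rng.normal(0, 0.01, n_frames)
    if spec.occluded_from is not None:
        occ = np.arange(n_frames) >= spec.occluded_from
        tracked[np.ix_(occ, _LOWER_JOINTS)] = False
        # an occluder close to the camera dominates the lower-body region
        lower_depth = np.where(occ, upper_depth - 0.6, lower_depth)
        # positions of occluded joints freeze at the last tracked estimate
        if 0 < spec.occluded_from < n_frames:
            pos[np.ix_(np.flatnonzero(occ), _LOWER_JOINTS)] = \
                pos[spec.occluded_from - 1, _LOWER_JOINTS]

    tag = spec.behavior if spec.combined_with is None else \
        f"{spec.behavior}+{spec.combined_with}"
    clip = SkeletonClip(pos, tracked, frame_rate=frame_rate, p_gt=spec.p_gt,
                        behavior=tag)
    profile = DepthProfile(upper_depth, lower_depth)
    return clip, profile


def generate_floor(tilt_deg: float = 0.0, extent: float = 3.0,
                   n_points: int = 400, noise_sd: float = 0.0,
                   outlier_frac: float = 0.0, seed: int = 0
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sample a floor point cloud at a given tilt with optional outliers.

    The floor plane passes through the origin with normal
    (sin(tilt), cos(tilt), 0) (a camera rolled about its z-axis).  Returns
    ``(points, true_normal)``.
    """
    if not 0.0 <= outlier_frac < 1.0:
        raise ValueError("outlier_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    tilt = math.radians(tilt_deg)
    normal = np.array([math.sin(tilt), math.cos(tilt), 0.0])
    e1 = np.array([math.cos(tilt), -math.sin(tilt), 0.0])
    e2 = np.array([0.0, 0.0, 1.0])
    n_out = int(round(outlier_frac * n_points))
    n_in = n_points - n_out
    a = rng.uniform(-extent / 2, extent / 2, n_in)
    b = rng.uniform(0.5, 0.5 + extent, n_in)
    pts = np.outer(a, e1) + np.outer(b, e2)
    if noise_sd > 0:
        pts = pts + np.outer(rng.normal(0.0, noise_sd, n_in), normal)
    if n_out:
        out = np.column_stack([rng.uniform(-extent, extent, n_out),
                               rng.uniform(0.1, 1.5, n_out),
                               rng.uniform(0.5, 0.5 + extent, n_out)])
        pts = np.vstack([pts, out])
    return pts, normal


# ---------------------------------------------------------------------------
# per-module calibration corpora
# ---------------------------------------------------------------------------

_CALIBRATION_RECIPES = {
    "push_up_climb": lambda i: (_Drivers(template=_climb_template("push", i)),
                                _quantize(0.55 + 0.35 * i)),
    "pull_up_climb": lambda i: (_Drivers(template=_climb_template("pull", i)),
                                _quantize(0.55 + 0.35 * i)),
    "run": lambda i: (_Drivers(speed=V_MAX * i),
                      _quantize(_label_sigmoid(V_MAX * i, "run"))),
    "jump": lambda i: (_Drivers(jump_amp=H_MAX * i),
                       _quantize(_label_sigmoid(H_MAX * i, "jump"))),
    "sway": lambda i: (_Drivers(sway_amp=SWAY_MAX * i),
                       _quantize(_label_sigmoid(SWAY_MAX * i, "sway"))),
    "lean": lambda i: (_Drivers(lean_static=LEAN_MAX * i),
                       _quantize(_label_sigmoid(LEAN_MAX * i, "lean"))),
    "foot_altitude": lambda i: (_Drivers(elevation=FURNITURE_H * i),
                                _quantize(_label_sigmoid(FURNITURE_H * i, "altitude"))),
    "head_altitude": lambda i: (_Drivers(elevation=FURNITURE_H * i),
                                _quantize(_label_sigmoid(FURNITURE_H * i, "altitude"))),
}


def generate_calibration_set(module: str, n: int = 20, seed: int = 0,
                             duration: float = 3.0, noise_sd: float = NOISE_SD,
                             frame_rate: float = 30.0
                             ) -> list[tuple[SkeletonClip, float]]:
    """Per-module sweep of labelled clips spanning the stimulus range.

    ``n`` single-driver clips at intensities evenly spaced over
    (0, 1], each labelled by the questionnaire rule; head-altitude clips are
    generated with fully occluded feet so the module engages.
    """
    if module not in _CALIBRATION_RECIPES:
        raise KeyError(f"unknown module: {module}")
    rng = np.random.default_rng(seed)
    intensities = np.linspace(0.05, 1.0, n)
    out = []
    n_frames = max(2, int(round(duration * frame_rate)))
    for i in intensities:
        drv, label = _CALIBRATION_RECIPES[module](float(i))
        pos = _build_positions(drv, n_frames, frame_rate)
        pos[:, :, 0] += rng.uniform(-0.5, 0.5)
        pos[:, :, 2] += rng.uniform(2.0, 3.0)
        pos += rng.normal(0.0, noise_sd, size=pos.shape)
        tracked = np.ones((n_frames, N_JOINTS), dtype=bool)
        if module == "head_altitude":
            tracked[:, _LOWER_JOINTS] = False
        clip = SkeletonClip(pos, tracked, frame_rate=frame_rate, p_gt=label,
                            behavior=f"calibration:{module}")
        out.append((clip, label))
    return out


# ---------------------------------------------------------------------------
# posture-classifier training corpora
# ---------------------------------------------------------------------------

def posture_training_set(posture: str, n_per_class: int = 90,
                         seed: int = 0) -> TrainingSet:
    """Labelled frame sets for the three posture SVMs.

    Positive frames come from the posture's own clips (climb variants at
    committed intensities, or seated clips); negatives are drawn from the
    other everyday behaviors so the classifier sees standing, locomotion,
    sitting and elevated poses.
    """
    rng = np.random.default_rng(seed)
    if posture in ("push_up_climb", "pull_up_climb"):
        variant = "push" if posture == "push_up_climb" else "pull"
        other = "pull" if variant == "push" else "push"
        pos_specs = [BehaviorSpec("climbing", intensity=float(i),
                                  climb_variant=variant,
                                  seed=int(rng.integers(2 ** 31)))
                     for i in np.linspace(0.4, 1.0, 15)]
        # negatives must span every non-climb posture (and the other climb
        # variant) across the camera frustum, or the classifier latches onto
        # where the body stands instead of how the arms are committed
        neg_pool = [b for b in BEHAVIORS if b != "climbing"]
        neg_specs = [BehaviorSpec(b, intensity=float(rng.uniform(0.2, 1.0)),
                                  seed=int(rng.integers(2 ** 31)))
                     for _ in range(2) for b in neg_pool]
        neg_specs += [BehaviorSpec("climbing", intensity=float(rng.uniform(0.4, 1.0)),
                                   climb_variant=other,
                                   seed=int(rng.integers(2 ** 31)))
                      for _ in range(3)]
    elif posture == "sitting":
        pos_specs = [BehaviorSpec("sitting", intensity=float(i),
                                  seed=int(rng.integers(2 ** 31)))
                     for i in np.linspace(0.2, 1.0, 15)]
        neg_pool = [b for b in BEHAVIORS if b != "sitting"]
        neg_specs = [BehaviorSpec(b, intensity=float(rng.uniform(0.2, 1.0)),
                                  seed=int(rng.integers(2 ** 31)))
                     for _ in range(2) for b in neg_pool]
        # elevated combinations look nothing like sitting but must not gate
        neg_specs += [BehaviorSpec("climbing", intensity=float(rng.uniform(0.5, 1.0)),
                                   combined_with="standing_on_furniture",
                                   seed=int(rng.integers(2 ** 31)))
                      for _ in range(3)]
    else:
        raise ValueError(f"unknown posture: {posture}")

    def frames_from(specs: Sequence[BehaviorSpec], n: int) -> np.ndarray:
        feats = []
        for s in specs:
            clip, _ = generate_clip(s)
            feats.append(clip_feature_matrix(clip.forward_filled()))
        X = np.vstack(feats)
        idx = rng.choice(X.shape[0], size=n, replace=X.shape[0] < n)
        return X[idx]

    X_pos = frames_from(pos_specs, n_per_class)
    X_neg = frames_from(neg_specs, n_per_class)
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(n_per_class, dtype=int),
                        -np.ones(n_per_class, dtype=int)])
    return TrainingSet(X, y)


# ---------------------------------------------------------------------------
# labelled corpora for fusion training / testing
# ---------------------------------------------------------------------------

_COMBO_PAIRS: tuple[tuple[str, str], ...] = (
    ("high_jumping", "tumbling"),
    ("climbing", "standing_on_furniture"),
    ("rush_running", "high_jumping"),
    ("tumbling", "high_jumping"),
    ("standing_on_furniture", "dancing"),
)

#: dataset intensity ranges keeping safe behaviors on the safe label side
_INTENSITY_RANGES: dict[str, tuple[float, float]] = {
    "sitting": (0.1, 1.0), "standing": (0.1, 1.0), "walking": (0.1, 0.7),
    "jumping_rope": (0.1, 1.0), "dancing": (0.1, 1.0),
    "rush_running": (0.5, 1.0), "high_jumping": (0.5, 1.0),
    "tumbling": (0.5, 1.0), "climbing": (0.5, 1.0),
    "standing_on_furniture": (0.5, 1.0),
}

DEFAULT_MIX: dict[str, float] = {"safe": 0.5, "risky": 0.35, "combined": 0.15}


@dataclass
class SyntheticDataset:
    """A labelled clip corpus with a stratified train/test split."""

    clips: list[SkeletonClip]
    profiles: list[DepthProfile]
    p_gt: np.ndarray
    behaviors: list[str]
    train_mask: np.ndarray
    specs: list[BehaviorSpec]

    @property
    def n(self) -> int:
        return len(self.clips)


def generate_dataset(n_clips: int = 200, mix: Optional[dict[str, float]] = None,
                     seed: int = 0) -> SyntheticDataset:
    """Generate a labelled corpus of single- and combined-behavior clips.

    ``mix`` gives the fractions of safe single behaviors, fall-risky single
    behaviors and combined-behavior clips (must sum to 1).  Behaviors cycle
    within each group, intensities are drawn from behavior-specific ranges,
    and labels follow the questionnaire rule (combined clips take the max
    component label + 0.1, capped at 1).  The train/test split is an even
    stratified half/half over the alarm classes.
    """
    mix = dict(mix or DEFAULT_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix fractions must sum to 1")
    counts = {k: int(round(v * n_clips)) for k, v in mix.items()}
    counts[next(iter(counts))] += n_clips - sum(counts.values())

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    specs: list[BehaviorSpec] = []
    for group, count in counts.items():
        for k in range(count):
            if group == "safe":
                b = SAFE_BEHAVIORS[k % len(SAFE_BEHAVIORS)]
                lo, hi = _INTENSITY_RANGES[b]
                specs.append(BehaviorSpec(b, intensity=float(rng.uniform(lo, hi)),
                                          seed=int(rng.integers(2 ** 31))))
            elif group == "risky":
                b = RISKY_BEHAVIORS[k % len(RISKY_BEHAVIORS)]
                lo, hi = _INTENSITY_RANGES[b]
                specs.append(BehaviorSpec(b, intensity=float(rng.uniform(lo, hi)),
                                          seed=int(rng.integers(2 ** 31))))
            elif group == "combined":
                a, b = _COMBO_PAIRS[k % len(_COMBO_PAIRS)]
                specs.append(BehaviorSpec(a, intensity=float(rng.uniform(0.5, 1.0)),
                                          combined_with=b,
                                          seed=int(rng.integers(2 ** 31))))
            else:
                raise ValueError(f"unknown mix group: {group}")
    order = rng.permutation(len(specs))
    specs = [specs[i] for i in order]

    clips, profiles, labels, behaviors = [], [], [], []
    for k, s in enumerate(specs):
        clip, profile = generate_clip(s)
        clip.clip_id = f"clip{k:03d}"
        clips.append(clip)
        profiles.append(profile)
        labels.append(s.p_gt)
        behaviors.append(clip.behavior)
    labels = np.asarray(labels)

    train_mask = np.zeros(len(specs), dtype=bool)
    for cls_mask in (labels > 0.5, labels <= 0.5):
        idx = np.flatnonzero(cls_mask)
        rng.shuffle(idx)
        train_mask[idx[: len(idx) // 2 + len(idx) % 2]] = True
    return SyntheticDataset(clips, profiles, labels, behaviors, train_mask, specs)
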