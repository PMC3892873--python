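"""Skeleton streams and per-frame kinematics.

A skeleton is the 20-joint body model delivered by consumer depth cameras
(Kinect v1 generation): four torso/head joints, four joints per limb.  All
quantities are in metres in a right-handed camera frame with y roughly "up";
streams run at a nominal 30 Hz and are consumed as short clips (3 s by
default).

This module owns the data model (:class:`SkeletonFrame`, :class:`SkeletonClip`)
and the kinematic primitives every risk module builds on: the 60-dimensional
per-frame feature vector, feature normalization, the bone-weighted body
centroid, the body height chain and the hip-to-shoulder spine vector.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

import numpy as np


class JointName(IntEnum):
    """The 20 skeletal joints, in the fixed feature order."""

    HIP_CENTER = 0
    SPINE = 1
    SHOULDER_CENTER = 2
    HEAD = 3
    SHOULDER_LEFT = 4
    ELBOW_LEFT = 5
    WRIST_LEFT = 6
    HAND_LEFT = 7
    SHOULDER_RIGHT = 8
    ELBOW_RIGHT = 9
    WRIST_RIGHT = 10
    HAND_RIGHT = 11
    HIP_LEFT = 12
    KNEE_LEFT = 13
    ANKLE_LEFT = 14
    FOOT_LEFT = 15
    HIP_RIGHT = 16
    KNEE_RIGHT = 17
    ANKLE_RIGHT = 18
    FOOT_RIGHT = 19


N_JOINTS = len(JointName)
FEATURE_DIM = 3 * N_JOINTS

#: The 19 bones of the skeleton tree (parent, child).
BONES: tuple[tuple[JointName, JointName], ...] = (
    (JointName.HIP_CENTER, JointName.SPINE),
    (JointName.SPINE, JointName.SHOULDER_CENTER),
    (JointName.SHOULDER_CENTER, JointName.HEAD),
    (JointName.SHOULDER_CENTER, JointName.SHOULDER_LEFT),
    (JointName.SHOULDER_LEFT, JointName.ELBOW_LEFT),
    (JointName.ELBOW_LEFT, JointName.WRIST_LEFT),
    (JointName.WRIST_LEFT, JointName.HAND_LEFT),
    (JointName.SHOULDER_CENTER, JointName.SHOULDER_RIGHT),
    (JointName.SHOULDER_RIGHT, JointName.ELBOW_RIGHT),
    (JointName.ELBOW_RIGHT, JointName.WRIST_RIGHT),
    (JointName.WRIST_RIGHT, JointName.HAND_RIGHT),
    (JointName.HIP_CENTER, JointName.HIP_LEFT),
    (JointName.HIP_LEFT, JointName.KNEE_LEFT),
    (JointName.KNEE_LEFT, JointName.ANKLE_LEFT),
    (JointName.ANKLE_LEFT, JointName.FOOT_LEFT),
    (JointName.HIP_CENTER, JointName.HIP_RIGHT),
    (JointName.HIP_RIGHT, JointName.KNEE_RIGHT),
    (JointName.KNEE_RIGHT, JointName.ANKLE_RIGHT),
    (JointName.ANKLE_RIGHT, JointName.FOOT_RIGHT),
)

assert len(BONES) == 19

_BONE_A = np.array([a for a, _ in BONES])
_BONE_B = np.array([b for _, b in BONES])

#: Torso segment of the height chain (head down to hip center).
_HEIGHT_TORSO = (
    (JointName.HEAD, JointName.SHOULDER_CENTER),
    (JointName.SHOULDER_CENTER, JointName.SPINE),
    (JointName.SPINE, JointName.HIP_CENTER),
)
#: Leg segments, averaged over sides.
_HEIGHT_LEGS = {
    "left": (
        (JointName.HIP_CENTER, JointName.HIP_LEFT),
        (JointName.HIP_LEFT, JointName.KNEE_LEFT),
        (JointName.KNEE_LEFT, JointName.ANKLE_LEFT),
        (JointName.ANKLE_LEFT, JointName.FOOT_LEFT),
    ),
    "right": (
        (JointName.HIP_CENTER, JointName.HIP_RIGHT),
        (JointName.HIP_RIGHT, JointName.KNEE_RIGHT),
        (JointName.KNEE_RIGHT, JointName.ANKLE_RIGHT),
        (JointName.ANKLE_RIGHT, JointName.FOOT_RIGHT),
    ),
}


class UntrackedJointError(ValueError):
    """Raised when an untracked joint is required and no fallback exists."""


@dataclass
class SkeletonFrame:
    """One time-stamped 20-joint pose.

    ``positions`` is a (20, 3) array in :class:`JointName` order; ``tracked``
    marks which joints the sensor actually observed (untracked joints carry a
    stale or sentinel position).
    """

    frame_index: int
    timestamp: float
    positions: np.ndarray
    tracked: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (N_JOINTS, 3):
            raise ValueError(f"positions must be ({N_JOINTS}, 3)")
        if self.tracked is None:
            self.tracked = np.ones(N_JOINTS, dtype=bool)
        self.tracked = np.asarray(self.tracked, dtype=bool)
        if self.tracked.shape != (N_JOINTS,):
            raise ValueError(f"tracked must have length {N_JOINTS}")
        if not np.all(np.isfinite(self.positions[self.tracked])):
            raise ValueError("tracked joint positions must be finite")

    @classmethod
    def from_mapping(
        cls,
        joints: Mapping[Union[JointName, str], Sequence[float]],
        frame_index: int = 0,
        timestamp: float = 0.0,
        tracked: Optional[Mapping[Union[JointName, str], bool]] = None,
    ) -> "SkeletonFrame":
        """Build a frame from a joint-name -> (x, y, z) mapping.

        The input mapping may be in any order; positions are stored in the
        fixed :class:`JointName` order.
        """
        pos = np.zeros((N_JOINTS, 3))
        trk = np.ones(N_JOINTS, dtype=bool)
        seen = np.zeros(N_JOINTS, dtype=bool)
        for key, xyz in joints.items():
            j = JointName[key] if isinstance(key, str) else JointName(key)
            pos[j] = np.asarray(xyz, dtype=float)
            seen[j] = True
        if not seen.all():
            missing = [JointName(i).name for i in np.flatnonzero(~seen)]
            raise ValueError(f"missing joints: {missing}")
        if tracked is not None:
            for key, flag in tracked.items():
                j = JointName[key] if isinstance(key, str) else JointName(key)
                trk[j] = bool(flag)
        return cls(frame_index, timestamp, pos, trk)

    def __getitem__(self, joint: JointName) -> np.ndarray:
        return self.positions[JointName(joint)]

    def is_tracked(self, joint: JointName) -> bool:
        return bool(self.tracked[JointName(joint)])


@dataclass
class SkeletonClip:
    """A time-ordered sequence of skeleton frames with optional labels.

    ``positions``: (T, 20, 3); ``tracked``: (T, 20) boolean; nominal length is
    90 frames at 30 Hz but any T >= 2 is accepted.  ``p_gt`` is an optional
    expert ground-truth fall risk in [0, 1] for the whole clip.
    """

    positions: np.ndarray
    tracked: Optional[np.ndarray] = None
    frame_rate: float = 30.0
    timestamps: Optional[np.ndarray] = None
    p_gt: Optional[float] = None
    behavior: Optional[str] = None
    clip_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (N_JOINTS, 3):
            raise ValueError(f"positions must be (T, {N_JOINTS}, 3)")
        T = self.positions.shape[0]
        if self.tracked is None:
            self.tracked = np.ones((T, N_JOINTS), dtype=bool)
        self.tracked = np.asarray(self.tracked, dtype=bool)
        if self.tracked.shape != (T, N_JOINTS):
            raise ValueError("tracked must be (T, 20)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(T) / self.frame_rate
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("frames must be time-ordered")
        if self.p_gt is not None and not (0.0 <= self.p_gt <= 1.0):
            raise ValueError("p_gt must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(i, float(self.timestamps[i]), self.positions[i], self.tracked[i])

    def frames(self) -> Iterator[SkeletonFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def forward_filled(self) -> "SkeletonClip":
        """Replace untracked joint positions by the joint's last tracked value.

        On-line semantics: only past frames of the same clip are used; a joint
        untracked from the very first frame keeps its sentinel position and
        stays flagged untracked.  Tracked flags are preserved so downstream
        gating still sees the occlusion.
        """
        pos = self.positions.copy()
        last = np.full((N_JOINTS, 3), np.nan)
        have = np.zeros(N_JOINTS, dtype=bool)
        for t in range(self.n_frames):
            trk = self.tracked[t]
            last[trk] = pos[t, trk]
            have |= trk
            fill = ~trk & have
            pos[t, fill] = last[fill]
        return replace(self, positions=pos, tracked=self.tracked.copy(),
                       timestamps=self.timestamps.copy())


@dataclass
class NormalizationStats:
    """Per-dimension mean/std for z-scoring the 60-vector features.

    Zero-variance dimensions get std 1 and are recorded in
    ``zero_variance``.
    """

    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.zero_variance is None:
            self.zero_variance = np.zeros_like(self.std, dtype=bool)
        if np.any(self.std <= 0):
            raise ValueError("std must be strictly positive")

    @classmethod
    def fit(cls, features: np.ndarray) -> "NormalizationStats":
        X = np.atleast_2d(np.asarray(features, dtype=float))
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        zero = std == 0.0
        std = np.where(zero, 1.0, std)
        return cls(mean, std, zero)

    @classmethod
    def identity(cls, dim: int = FEATURE_DIM) -> "NormalizationStats":
        return cls(np.zeros(dim), np.ones(dim))


def frame_feature_vector(frame: SkeletonFrame) -> np.ndarray:
    """Concatenate the (x, y, z) of the 20 joints in the fixed enum order.

    Raises :class:`UntrackedJointError` if any joint is untracked -- callers
    working on clips should forward-fill first
    (:meth:`SkeletonClip.forward_filled`).
    """
    if not frame.tracked.all():
        missing = [JointName(i).name for i in np.flatnonzero(~frame.tracked)]
        raise UntrackedJointError(f"untracked joint, no fallback: {missing}")
    return frame.positions.reshape(-1).copy()


def clip_feature_matrix(clip: SkeletonClip) -> np.ndarray:
    """(T, 60) feature matrix for a (forward-filled) clip."""
    return clip.positions.reshape(clip.n_frames, FEATURE_DIM)


def normalize(features: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Elementwise (f - mean) / std."""
    return (np.asarray(features, dtype=float) - stats.mean) / stats.std


def denormalize(features: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return np.asarray(features, dtype=float) * stats.std + stats.mean


def _bone_centroid(points_a: np.ndarray, points_b: np.ndarray,
                   mask: Optional[np.ndarray] = None,
                   weighted: bool = True) -> np.ndarray:
    """Centre of mass of a set of uniform rods given their endpoints.

    ``points_a``/``points_b``: (..., n, 3); ``mask``: (..., n) booleans of
    usable rods.  Falls back to the unweighted mean of midpoints when the
    total length vanishes (all joints coincident).
    """
    mid = 0.5 * (points_a + points_b)
    if mask is None:
        mask = np.ones(mid.shape[:-1], dtype=bool)
    if weighted:
        w = np.where(mask, np.linalg.norm(points_b - points_a, axis=-1), 0.0)
    else:
        w = mask.astype(float)
    total = w.sum(axis=-1, keepdims=True)
    degenerate = total[..., 0] < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (w[..., None] * mid).sum(axis=-2) / total
    if np.any(degenerate):
        wf = mask.astype(float)
        fallback = (wf[..., None] * mid).sum(axis=-2) / np.maximum(
            wf.sum(axis=-1, keepdims=True), 1.0)
        out = np.where(np.atleast_1d(degenerate)[..., None], fallback, out)
    return out


def body_centroid(frame: SkeletonFrame, weighted: bool = True) -> np.ndarray:
    """Centre of mass of the 19 bones (uniform-rod model).

    Bone midpoints are averaged with weights proportional to bone length (set
    ``weighted=False`` for the plain midpoint average).  Bones with an
    untracked endpoint are dropped; the centroid is then computed over the
    remaining bones (a partial estimate).
    """
    a = frame.positions[_BONE_A]
    b = frame.positions[_BONE_B]
    mask = frame.tracked[_BONE_A] & frame.tracked[_BONE_B]
    if not mask.any():
        raise UntrackedJointError("no tracked bone for centroid")
    return _bone_centroid(a[None], b[None], mask[None], weighted=weighted)[0]


def clip_centroids(clip: SkeletonClip, weighted: bool = True) -> np.ndarray:
    """(T, 3) per-frame body centroids for a clip."""
    a = clip.positions[:, _BONE_A, :]
    b = clip.positions[:, _BONE_B, :]
    mask = clip.tracked[:, _BONE_A] & clip.tracked[:, _BONE_B]
    return _bone_centroid(a, b, mask, weighted=weighted)


def body_height(frame: SkeletonFrame) -> float:
    """Body height H as the summed head-to-foot bone chain.

    H = |HEAD-SHOULDER_CENTER| + |SHOULDER_CENTER-SPINE| + |SPINE-HIP_CENTER|
    plus the left/right average of the hip-to-foot leg chain.
    """
    chain_joints = {j for seg in _HEIGHT_TORSO for j in seg}
    for leg in _HEIGHT_LEGS.values():
        chain_joints |= {j for seg in leg for j in seg}
    if not all(frame.tracked[j] for j in chain_joints):
        raise UntrackedJointError("height unavailable: chain joint untracked")
    h = sum(float(np.linalg.norm(frame[a] - frame[b])) for a, b in _HEIGHT_TORSO)
    leg_lengths = []
    for segs in _HEIGHT_LEGS.values():
        leg_lengths.append(sum(float(np.linalg.norm(frame[a] - frame[b])) for a, b in segs))
    return h + float(np.mean(leg_lengths))


def clip_heights(clip: SkeletonClip) -> np.ndarray:
    """(T,) per-frame body heights (vectorized :func:`body_height`)."""
    def seg(a: JointName, b: JointName) -> np.ndarray:
        return np.linalg.norm(clip.positions[:, a] - clip.positions[:, b], axis=-1)

    torso = sum(seg(a, b) for a, b in _HEIGHT_TORSO)
    legs = [sum(seg(a, b) for a, b in segs) for segs in _HEIGHT_LEGS.values()]
    return torso + 0.5 * (legs[0] + legs[1])


def spine_vector(frame: SkeletonFrame) -> np.ndarray:
    """The hip-center -> shoulder-center vector (the body 'spine')."""
    if not (frame.tracked[JointName.HIP_CENTER] and frame.tracked[JointName.SHOULDER_CENTER]):
        raise UntrackedJointError("spine unavailable: endpoint untracked")
    return frame[JointName.SHOULDER_CENTER] - frame[JointName.HIP_CENTER]


def clip_spine_vectors(clip: SkeletonClip) -> np.ndarray:
    return clip.positions[:, JointName.SHOULDER_CENTER] - clip.positions[:, JointName.HIP_CENTER]


# ---------------------------------------------------------------------------
# I/O: JSON-lines and flat CSV skeleton stream formats
# ---------------------------------------------------------------------------

def write_clip_jsonl(clip: SkeletonClip, path: Union[str, Path]) -> None:
    """Write a clip as JSON lines: a header record then one record per frame."""
    path = Path(path)
    with path.open("w") as fh:
        header = {"frame_rate": clip.frame_rate}
        if clip.p_gt is not None:
            header["p_gt"] = clip.p_gt
        if clip.behavior is not None:
            header["behavior"] = clip.behavior
        if clip.clip_id is not None:
            header["clip_id"] = clip.clip_id
        fh.write(json.dumps(header) + "\n")
        for t in range(clip.n_frames):
            rec = {"frame": t, "t": float(clip.timestamps[t])}
            for j in JointName:
                x, y, z = clip.positions[t, j]
                rec[j.name] = [round(float(x), 6), round(float(y), 6),
                               round(float(z), 6), int(clip.tracked[t, j])]
            fh.write(json.dumps(rec) + "\n")


def read_clip_jsonl(path: Union[str, Path]) -> SkeletonClip:
    path = Path(path)
    with path.open() as fh:
        lines = [json.loads(line) for line in fh if line.strip()]
    if not lines:
        raise ValueError(f"empty clip file: {path}")
    header = lines[0]
    frames = lines[1:] if "frame_rate" in header else lines
    if "frame_rate" not in header:
        header = {"frame_rate": 30.0}
    T = len(frames)
    pos = np.zeros((T, N_JOINTS, 3))
    trk = np.ones((T, N_JOINTS), dtype=bool)
    ts = np.zeros(T)
    for t, rec in enumerate(frames):
        ts[t] = rec.get("t", t / header["frame_rate"])
        for j in JointName:
            x, y, z, tracked = rec[j.name]
            pos[t, j] = (x, y, z)
            trk[t, j] = bool(tracked)
    return SkeletonClip(pos, trk, frame_rate=float(header["frame_rate"]),
                        timestamps=ts, p_gt=header.get("p_gt"),
                        behavior=header.get("behavior"), clip_id=header.get("clip_id"))


def write_clip_csv(clip: SkeletonClip, path: Union[str, Path]) -> None:
    """Flat CSV dialect: one row per (frame, joint)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "joint", "x", "y", "z", "tracked"])
        for t in range(clip.n_frames):
            for j in JointName:
                x, y, z = clip.positions[t, j]
                writer.writerow([t, j.name, f"{x:.6f}", f"{y:.6f}", f"{z:.6f}",
                                 int(clip.tracked[t, j])])


def read_clip_csv(path: Union[str, Path], frame_rate: float = 30.0,
                  p_gt: Optional[float] = None,
                  behavior: Optional[str] = None) -> SkeletonClip:
    path = Path(path)
    rows: dict[int, dict[str, tuple]] = {}
    with path.open(newline="") as fh:
        for rec in csv.DictReader(fh):
            t = int(rec["frame"])
            rows.setdefault(t, {})[rec["joint"]] = (
                float(rec["x"]), float(rec["y"]), float(rec["z"]),
                bool(int(rec["tracked"])))
    T = max(rows) + 1
    pos = np.zeros((T, N_JOINTS, 3))
    trk = np.ones((T, N_JOINTS), dtype=bool)
    for t, joints in rows.items():
        for name, (x, y, z, tracked) in joints.items():
            j = JointName[name]
            pos[t, j] = (x, y, z)
            trk[t, j] = tracked
    return SkeletonClip(pos, trk, frame_rate=frame_rate, p_gt=p_gt, behavior=behavior)


def read_clip(path: Union[str, Path]) -> SkeletonClip:
    """Read a clip, dispatching on the file extension (.jsonl/.json or .csv)."""
    path = Path(path)
    if path.suffix in (".jsonl", ".json"):
        return read_clip_jsonl(path)
    if path.suffix == ".csv":
        return read_clip_csv(path)
    raise ValueError(f"unknown clip format: {path.suffix}")
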