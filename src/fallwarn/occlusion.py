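"""Lower-body occlusion detection and tracking-mode switching.

When furniture hides the toddler's lower body, the depth readings in the
lower half of the skeleton area drop suddenly (the occluder is closer to the
camera).  A per-frame depth-profile summary -- mean depth of the upper- and
lower-body regions, split at hip height -- drives a debounced two-state
switch between the default 20-joint tracking mode and a seated 10-joint
upper-body mode.  While seated, the body-sway and foot-altitude modules are
disabled (their joints cannot be trusted).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

MODE_DEFAULT = "default"
MODE_SEATED = "seated"

#: Modules that must be gated off while in seated mode.
SEATED_DISABLED_MODULES = ("sway", "foot_altitude")


@dataclass
class DepthProfile:
    """Per-frame mean depths (metres) of the upper- and lower-body regions.

    NaN in ``lower`` marks frames whose lower-body region is entirely
    missing from the depth map (fully occluded).
    """

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        if self.upper.shape != self.lower.shape:
            raise ValueError("upper and lower must have equal length")
        if np.any(self.upper[~np.isnan(self.upper)] <= 0):
            raise ValueError("depths must be positive where present")

    @property
    def n_frames(self) -> int:
        return self.upper.shape[0]

    def to_csv(self, path: Union[str, Path]) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "upper_mean_depth", "lower_mean_depth"])
            for t in range(self.n_frames):
                lower = "" if np.isnan(self.lower[t]) else f"{self.lower[t]:.4f}"
                writer.writerow([t, f"{self.upper[t]:.4f}", lower])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DepthProfile":
        upper, lower = [], []
        with Path(path).open(newline="") as fh:
            for rec in csv.DictReader(fh):
                upper.append(float(rec["upper_mean_depth"]))
                raw = rec["lower_mean_depth"]
                lower.append(float(raw) if raw not in ("", None) else np.nan)
        return cls(np.asarray(upper), np.asarray(lower))


def detect_occlusion(profile: DepthProfile, delta: float = 0.3,
                     hold: int = 3) -> np.ndarray:
    """Per-frame tracking mode from the depth profile, debounced.

    A frame is "suspect" when the lower-body mean depth sits more than
    ``delta`` metres closer than the upper body (or is missing entirely).
    The mode flips to seated at frame t once the previous ``hold`` frames
    were all suspect, and back to default once the previous ``hold`` frames
    were all clear -- so isolated one-frame dips never switch the mode.

    Returns an array of ``"default"`` / ``"seated"`` strings.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if hold < 1:
        raise ValueError("hold must be >= 1")
    diff = profile.upper - profile.lower
    suspect = np.isnan(profile.lower) | (diff > delta)
    T = profile.n_frames
    modes = np.empty(T, dtype=object)
    state = MODE_DEFAULT
    for t in range(T):
        if t >= hold:
            window = suspect[t - hold:t]
            if state == MODE_DEFAULT and window.all():
                state = MODE_SEATED
            elif state == MODE_SEATED and not window.any():
                state = MODE_DEFAULT
        modes[t] = state
    return modes.astype(str)


def seated_mask(modes: np.ndarray) -> np.ndarray:
    """Boolean gate mask (True where the seated mode is active)."""
    return np.asarray(modes) == MODE_SEATED
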