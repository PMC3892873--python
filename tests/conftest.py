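import numpy as np
import pytest

from fallwarn.floor import FloorPlane
from fallwarn.skeleton import JointName, N_JOINTS, SkeletonFrame


@pytest.fixture
def horizontal_plane() -> FloorPlane:
    return FloorPlane.horizontal()


def make_frame(positions=None, tracked=None, **joint_overrides) -> SkeletonFrame:
    """A frame with all joints at the origin unless overridden by name."""
    pos = np.zeros((N_JOINTS, 3)) if positions is None else np.array(positions, dtype=float)
    for name, xyz in joint_overrides.items():
        pos[JointName[name.upper()]] = xyz
    return SkeletonFrame(0, 0.0, pos, tracked if tracked is not None
                         else np.ones(N_JOINTS, dtype=bool))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_pose(rng: np.random.Generator, scale: float = 0.5) -> np.ndarray:
    """A random (20, 3) joint cloud (not anatomically plausible; geometry only)."""
    return rng.normal(0.0, scale, size=(N_JOINTS, 3))
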