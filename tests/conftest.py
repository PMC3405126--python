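import numpy as np
import pytest

from drillnav import TrackedPose, VoxelVolume, build_drill_bit


@pytest.fixture(scope="session")
def sphere_bit():
    """4 mm spherical bit sampled at 0.2 mm."""
    return build_drill_bit("sphere", 4.0, 0.2)


@pytest.fixture()
def uniform_volume():
    """64^3 bone block, 0.4 mm isotropic voxels, origin at zero."""
    return VoxelVolume(
        np.full((64, 64, 64), 1500.0, dtype=np.float32),
        np.diag([0.4, 0.4, 0.4, 1.0]),
    )


def make_pose(tip, shaft=(0.0, 0.0, 1.0), t=0.0):
    tip = np.asarray(tip, dtype=float)
    u = np.asarray(shaft, dtype=float)
    u = u / np.linalg.norm(u)
    return TrackedPose(t=t, tip=tip, hind=tip + 100.0 * u)


@pytest.fixture()
def pose_factory():
    return make_pose
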