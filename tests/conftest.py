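import numpy as np
import pytest

from ergokit.skeleton import Keypoint, PoseFrame, Visibility
from ergokit.synthetic import PoseRecipe, generate_pose


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neutral_frame():
    """Standing pose, arms down, elbows at 80 deg, legs supported."""
    return generate_pose(PoseRecipe(seed=7))


@pytest.fixture
def stooped_frame():
    """A clearly non-neutral working posture."""
    return generate_pose(
        PoseRecipe(
            upper_arm_flexion=95.0,
            elbow_flexion=30.0,
            wrist_flexion=20.0,
            neck_flexion=25.0,
            trunk_flexion=30.0,
            seed=7,
        )
    )


def make_frame(points, skeleton="dywhse25", timestamp=0.0):
    """Frame from a {joint: (x, y, z)} mapping; z=None gives a 2D point."""
    kps = {}
    for name, p in points.items():
        if p is None:
            kps[name] = Keypoint.absent()
        else:
            x, y, *rest = p
            z = rest[0] if rest else None
            kps[name] = Keypoint(x=float(x), y=float(y), z=None if z is None else float(z))
    return PoseFrame(skeleton=skeleton, keypoints=kps, timestamp=timestamp)
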