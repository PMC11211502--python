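import numpy as np
import pytest

from gloveforge import default_model
from gloveforge.hand_model import Pose


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_inlimit_pose(model, rng):
    """A pose with every joint uniformly inside 80% of its limit range."""

    def make(generator=None):
        g = generator if generator is not None else rng
        angles = {}
        for j in model.joints:
            lo, hi = j.limits
            mid, half = (lo + hi) / 2, (hi - lo) / 2
            angles[j.name] = g.uniform(mid - 0.8 * half, mid + 0.8 * half)
        return Pose(angles)

    return make
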