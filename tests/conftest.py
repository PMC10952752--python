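import numpy as np
import pytest

from fetaltrack import (
    AcquisitionConfig,
    GridGeometry,
    MotionEvent,
    VolumeGrid,
    make_sphere_world,
    step_trajectory,
)


@pytest.fixture
def geom64():
    """Desk-scale phantom grid: 64^3 voxels at 3 mm, centered at the origin."""
    return GridGeometry((64, 64, 64), 3.0, (0.0, 0.0, 0.0))


@pytest.fixture
def sphere_scene():
    return make_sphere_world(radius_mm=40.0)


@pytest.fixture
def noise_free_acq():
    return AcquisitionConfig(noise_sigma=0.0)


@pytest.fixture
def step_x_trajectory():
    """One +9 mm x-step first visible at repetition 6 (0-based), 50 reps."""
    return step_trajectory([MotionEvent(6, (9.0, 0.0, 0.0))], 50)


@pytest.fixture
def random_volume(geom64):
    rng = np.random.default_rng(7)
    return VolumeGrid(geom64, rng.random(geom64.shape, dtype=np.float32))


def brute_force_gdl(probs, onehot, eps=1e-5):
    """Independent double-loop evaluation of the weighted-Dice objective.

    Exact summation (math.fsum) so the oracle itself carries no float error.
    """
    import math

    M = probs.shape[0]
    p = probs.reshape(M, -1)
    t = onehot.reshape(M, -1)
    num_terms = []
    den_terms = []
    for k in range(M):
        w = 1.0 / max(math.fsum(t[k]), eps) ** 2
        for n in range(p.shape[1]):
            num_terms.append(w * p[k, n] * t[k, n])
            den_terms.append(w * (p[k, n] + t[k, n]))
    return 1.0 - 2.0 * math.fsum(num_terms) / math.fsum(den_terms)
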