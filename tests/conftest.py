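import numpy as np
import pytest

from chromodyn import synthdata


@pytest.fixture(scope="session")
def small_timelapse():
    """5-frame rendered stack with ground truth (shared; treat as read-only)."""
    params = synthdata.TimelapseParams(n_frames=5, n_foci=4, seed=11)
    stack, truth = synthdata.simulate_timelapse(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def medip_sim():
    """Default two-channel enrichment simulation (shared; read-only)."""
    params = synthdata.MedipSimParams(seed=21)
    return params, synthdata.simulate_medip(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A uniform random 3D rotation matrix and translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.uniform(-5.0, 5.0, size=3)
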