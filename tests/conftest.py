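import numpy as np
import pytest

from microrheo.io import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_trajectory(positions, dt=1.0, box=None, roles=None, probe_ids=None):
    """Assemble a Trajectory from a (n_frames, n, 3) array."""
    positions = np.asarray(positions, float)
    nf, n, _ = positions.shape
    if roles is None:
        roles = np.array(["probe_bead"] * n, dtype=object)
    if probe_ids is None:
        probe_ids = np.arange(n)
    return Trajectory(times=dt * np.arange(nf), positions=positions,
                      roles=np.asarray(roles, object),
                      probe_ids=np.asarray(probe_ids, int),
                      box=None if box is None else np.asarray(box, float),
                      periodic=np.array([box is not None] * 3))


@pytest.fixture
def random_walk_traj(rng):
    """Single 3D random walk, 4096 frames, free space."""
    steps = rng.normal(0, 0.5, size=(4095, 1, 3))
    pos = np.concatenate([np.zeros((1, 1, 3)), np.cumsum(steps, 0)], 0)
    return make_trajectory(pos, dt=0.01)
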