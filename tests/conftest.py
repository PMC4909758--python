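import numpy as np
import pytest

import bgconnect as bg


@pytest.fixture(scope="session")
def paper_phantom():
    """A small paper-like phantom shared across tests (coarse 0.1 mm step
    keeps the suite fast; visit sequences are step-invariant well below the
    0.5 mm voxel size)."""
    spec = bg.paper_like_spec(n_tracks=150, rng_seed=7, step=0.1)
    return bg.make_phantom(spec)


@pytest.fixture(scope="session")
def identity_volume():
    """A 12^3 volume with identity affine and two labelled blocks."""
    grid = np.zeros((12, 12, 12), dtype=np.int32)
    grid[2:5, 2:5, 2:5] = 3
    grid[8:11, 8:11, 8:11] = 5
    return bg.LabelVolume(grid, np.eye(4))


def brute_force_visits(points, volume):
    """Independent per-vertex label lookup + manual run compression.

    Deliberately written as a plain Python loop so it shares no code with
    the vectorised implementation it checks.
    """
    inv = np.linalg.inv(volume.affine)
    labels = []
    for p in points:
        v = inv[:3, :3] @ p + inv[:3, 3]
        idx = tuple(int(np.trunc(x + (0.5 if x >= 0 else -0.5))) for x in v)
        if all(0 <= idx[d] < volume.grid.shape[d] for d in range(3)):
            labels.append(int(volume.grid[idx]))
        else:
            labels.append(0)
    visits = []
    prev = 0
    start = None
    for i, l in enumerate(labels):
        if l != prev:
            if prev != 0:
                visits.append((prev, start, i - 1))
            start = i if l != 0 else None
            prev = l
    if prev != 0:
        visits.append((prev, start, len(labels) - 1))
    return visits
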