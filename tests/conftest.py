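import numpy as np
import pytest

from handlat.space import LEFT, RIGHT, SurfaceSpace
from handlat.synth import GeneratorParams, generate_space


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_space(rng):
    """Random two-hemisphere cloud, 30 vertices per side."""
    left = rng.normal(scale=30, size=(30, 3))
    left[:, 0] = -np.abs(left[:, 0]) - 1
    right = left.copy()
    right[:, 0] = -right[:, 0]
    coords = np.vstack([left, right])
    hemi = np.array([LEFT] * 30 + [RIGHT] * 30, dtype=np.int8)
    return SurfaceSpace(coords=coords, hemisphere=hemi)


@pytest.fixture(scope="session")
def tiny_params():
    return GeneratorParams(n_vertices_per_hemi=80, n_frames=96, seed=7)


@pytest.fixture(scope="session")
def tiny_gspace(tiny_params):
    return generate_space(tiny_params)


def brute_force_counts(data, threshold, sign="positive", hemi=None, scope="global"):
    """Independent oracle: full correlation matrix, then threshold and count."""
    data = np.asarray(data, float)
    sd = data.std(axis=1)
    R = np.zeros((len(data), len(data)))
    ok = sd > 0
    if ok.sum() >= 2:
        sub = np.corrcoef(data[ok])
        R[np.ix_(ok, ok)] = sub
    np.fill_diagonal(R, 0.0)
    edges = R > threshold if sign == "positive" else R < -threshold
    if scope == "global":
        return edges.sum(axis=1)
    hemi = np.asarray(hemi)
    same = hemi[:, None] == hemi[None, :]
    if scope == "ipsi":
        return (edges & same).sum(axis=1)
    return (edges & ~same).sum(axis=1)
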