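import numpy as np
import pytest

from rmsdalign import Mapping, PointSequence, RigidTransform
from rmsdalign.synthetic import lattice_rotations


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_integral_pair(rng, n, m, lo=-5, hi=5):
    """Random integer-coordinate instance (used all over the suite)."""
    P = PointSequence(rng.integers(lo, hi + 1, size=(n, 3)).astype(float),
                      integral=True)
    Q = PointSequence(rng.integers(lo, hi + 1, size=(m, 3)).astype(float),
                      integral=True)
    return P, Q


def random_lattice_transform(rng, span=5):
    """Integer-exact rigid transform: signed-permutation rotation + int shift."""
    rots = lattice_rotations()
    R = rots[rng.integers(len(rots))]
    t = rng.integers(-span, span + 1, size=3).astype(float)
    return RigidTransform(R, t)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


@pytest.fixture
def identity_mapping():
    return Mapping.identity
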