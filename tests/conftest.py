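import numpy as np
import pytest

from bvsign import BivariateSample, ScoreSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_blumen_sample():
    """Two points at angles pi/4 and 3pi/4, both above the axis."""
    return BivariateSample(points=[(1.0, 1.0), (-1.0, 1.0)])


@pytest.fixture
def decoupled_system():
    """Unit scores on disjoint coordinates: the joint CGF separates exactly."""
    return ScoreSystem(U=[(1.0, 0.0), (0.0, 1.0)], C=(-0.5, -0.5))


def random_sample(rng, n):
    return BivariateSample(points=rng.standard_normal((n, 2)))


def random_centered_system(rng, n):
    U = rng.normal(size=(n, 2))
    return ScoreSystem(U=U, C=-0.5 * U.sum(axis=0))


def brown_gradient_double_sum(points):
    """Brute-force double-sum gradient vector at the origin.

    q = (1/2n) sum_{i<j} sign(det[z_i z_j]) (rot90(z_j) - rot90(z_i))
    with rot90(a, b) = (-b, a); an independent oracle for the cyclic-sum
    construction of the Brown score system.
    """
    z = np.asarray(points, dtype=float)
    n = len(z)
    q = np.zeros(2)
    for i in range(n - 1):
        for j in range(i + 1, n):
            det = z[i, 0] * z[j, 1] - z[j, 0] * z[i, 1]
            rot_i = np.array([-z[i, 1], z[i, 0]])
            rot_j = np.array([-z[j, 1], z[j, 0]])
            q += np.sign(det) * (rot_j - rot_i)
    return q / (2.0 * n)


def enumerate_statistics(system):
    """All 2^n attainable values of B, one row per indicator vector."""
    n = system.n
    codes = np.arange(1 << n, dtype=np.uint64)
    bits = (codes[:, None] >> np.arange(n, dtype=np.uint64)) & np.uint64(1)
    return bits.astype(float) @ system.U + system.C
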