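import numpy as np
import pytest

from dmdmotion import MotionSequence, linear_system_series, planar_rotation


def random_linear_system(m: int, seed: int, radius: float = 0.95) -> np.ndarray:
    """Random m x m propagator rescaled to the given spectral radius."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(m, m))
    A *= radius / np.max(np.abs(np.linalg.eigvals(A)))
    return A


def random_linear_series(m: int, n: int, seed: int, radius: float = 0.95) -> MotionSequence:
    rng = np.random.default_rng(seed + 1_000_000)
    A = random_linear_system(m, seed, radius)
    x0 = rng.normal(size=m)
    return linear_system_series(A, x0, n)


def match_eigenvalues(a: np.ndarray, b: np.ndarray) -> float:
    """Greedy nearest-neighbour matching distance between two eigenvalue multisets."""
    a, b = list(a), list(b)
    assert len(a) == len(b), f"multiset sizes differ: {len(a)} vs {len(b)}"
    worst = 0.0
    for z in a:
        dists = [abs(z - w) for w in b]
        i = int(np.argmin(dists))
        worst = max(worst, dists[i])
        b.pop(i)
    return worst


@pytest.fixture
def decaying_diag_series() -> MotionSequence:
    """x_{k+1} = diag(0.9, 0.5) x_k from x_1 = (1, 1), three frames."""
    return linear_system_series(np.diag([0.9, 0.5]), [1.0, 1.0], 3)


@pytest.fixture
def rotation_scalar_series() -> MotionSequence:
    """Scalar cosine observable of a period-10 planar rotation, 50 frames."""
    full = linear_system_series(planar_rotation(2 * np.pi / 10), [1.0, 0.0], 50)
    return full.select_channels([0])
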