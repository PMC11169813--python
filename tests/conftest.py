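import numpy as np
import pytest

from spdalign import geometry as geo
from spdalign.data import SPDDataset


def random_spd(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix."""
    A = rng.standard_normal((n, n))
    return geo.symmetrize(scale * (A @ A.T) + n * scale * np.eye(n))


def random_sym(rng: np.random.Generator, n: int, scale: float = 1.0) -> np.ndarray:
    return geo.symmetrize(scale * rng.standard_normal((n, n)))


def random_spd_stack(rng, N, n, scale: float = 1.0) -> np.ndarray:
    return np.stack([random_spd(rng, n, scale) for _ in range(N)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def spd_pair(rng):
    return random_spd(rng, 4), random_spd(rng, 4)


@pytest.fixture
def diagonal_dataset():
    """Commuting (diagonal) two-class dataset."""
    rng = np.random.default_rng(3)
    mats = np.stack([np.diag(np.exp(rng.normal(0, 0.5, 3))) for _ in range(20)])
    labels = np.r_[np.ones(10), 2 * np.ones(10)].astype(int)
    return SPDDataset(mats, labels, "diag")


@pytest.fixture
def random_dataset(rng):
    mats = random_spd_stack(rng, 15, 4)
    labels = (np.arange(15) % 3) + 1
    return SPDDataset(mats, labels, "rand")
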