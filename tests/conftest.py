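import numpy as np
import pytest

from s6lattice import cell_to_basis, e3_to_s6, reduce_basis
from s6lattice.fixtures import random_cell


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_reduced_s6(rng: np.random.Generator, length_range=(2.0, 50.0)) -> np.ndarray:
    """Selling scalars of a random Selling-reduced cell."""
    basis = cell_to_basis(random_cell(rng, length_range))
    return reduce_basis(basis).s_reduced


def random_unimodular(rng: np.random.Generator, n_shears: int = 6) -> np.ndarray:
    """Random integer matrix with det +/-1, built from shears and swaps."""
    m = np.eye(3, dtype=np.int64)
    for _ in range(n_shears):
        i, j = rng.choice(3, size=2, replace=False)
        shear = np.eye(3, dtype=np.int64)
        shear[i, j] = rng.integers(-3, 4)
        m = m @ shear
        if rng.random() < 0.3:
            perm = rng.permutation(3)
            m = m[perm]
    return m
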