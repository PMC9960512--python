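import numpy as np
import pytest

from measd.io_hsi import SpectralCube
from measd.similarity import compute_similarity
from measd.synthetic import SyntheticSpec, generate_block_cube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cube(rng):
    """Unstructured 8-pixel x 6-band cube for unit-level checks."""
    return SpectralCube(rng.random((8, 6)))


@pytest.fixture(scope="session")
def planted_small():
    """L=10 cube with 3/3/4 planted groups, plus its affinity matrix."""
    spec = SyntheticSpec(
        L=10, N=100, true_boundaries=(3, 6), within_noise=0.005,
        between_sep=0.05, seed=42,
    )
    cube, truth = generate_block_cube(spec)
    W = compute_similarity(cube, d=7)
    return cube, truth, W


@pytest.fixture(scope="session")
def planted_medium():
    """L=30 cube with five equal planted groups (default conditions)."""
    spec = SyntheticSpec(seed=42)
    cube, truth = generate_block_cube(spec)
    W = compute_similarity(cube, d=7)
    return cube, truth, W


def scalar_fitness_oracle(omega, boundaries, include_diagonal=True, adjacent_only=False):
    """Triple-loop reference for the partition score; independent of the
    integral-image implementation."""
    L = omega.shape[0]
    edges = [0, *boundaries, L]
    K = len(edges) - 1
    total = 0.0
    for k in range(K):
        members = list(range(edges[k], edges[k + 1]))
        adjacent = []
        if k > 0:
            adjacent += list(range(edges[k - 1], edges[k]))
        if k < K - 1:
            adjacent += list(range(edges[k + 1], edges[k + 2]))
        within = 0.0
        for i in members:
            for j in members:
                if i == j and not include_diagonal:
                    continue
                within += omega[i, j]
        cross = 0.0
        for i in members:
            for j in adjacent:
                cross += omega[i, j]
        denom = cross if adjacent_only else within + cross
        total += within / denom
    return total
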