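"""Boundary-encoded partitions of the band axis and their fitness.

A chromosome is a vector of ``D = K - 1`` continuous genes.  Decoding
rounds, clips to ``[1, L-1]``, sorts and repairs duplicates, yielding
strictly increasing integer boundaries; boundary ``b`` means "band ``b``
starts the next subspace", so a chromosome always induces ``K`` non-empty,
contiguous, half-open subspaces covering ``[0, L)``.

The partition score is a normalized-association (NA) ratio restricted to
*adjacent* subspaces.  Classic NA normalizes each cluster's within-affinity
by its total affinity to the whole band axis; here the normalizing universe
is local — the subspace itself plus its immediate spectral neighbors — so
the score concentrates on separating each subspace from its neighbors,
where redundant band picks would come from.  Each term lies in (0, 1] and
the sum is bounded by K, maximized when subspaces are internally
homogeneous and decoupled from their neighbors.

A strictly-adjacent denominator (neighbor pairs only, without the within
pairs) is also available; that variant is unbounded and degenerates on
blocked affinity matrices — a large subspace flanked by a single-band one
gets an arbitrarily small denominator — so it is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .similarity import SimilarityMatrix

# affinities between far-apart bands can underflow to exactly 0.0; keep the
# neighbor-affinity denominator positive so fitness stays finite
_DENOM_FLOOR = 1e-300


@dataclass(frozen=True)
class Partition:
    """K contiguous half-open band-index ranges covering ``[0, L)``."""

    boundaries: tuple[int, ...]  # strictly increasing, in [1, L-1]
    L: int

    def __post_init__(self) -> None:
        b = self.boundaries
        if any(not 1 <= x <= self.L - 1 for x in b):
            raise ValueError(f"boundaries {b} out of range [1, {self.L - 1}]")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"boundaries {b} not strictly increasing")

    @property
    def K(self) -> int:
        return len(self.boundaries) + 1

    @cached_property
    def subspaces(self) -> tuple[tuple[int, int], ...]:
        edges = (0, *self.boundaries, self.L)
        return tuple((edges[k], edges[k + 1]) for k in range(self.K))


def decode(genes: np.ndarray, L: int) -> Partition:
    """Decode a continuous chromosome to a feasible boundary partition.

    Round to the nearest integer, clip to ``[1, L-1]``, sort, then repair
    duplicates deterministically: the later duplicate moves to the smallest
    free slot above it, wrapping downward to the largest free slot below
    when the top of the range is occupied.  Idempotent on already-feasible
    integer chromosomes and invariant to gene order.
    """
    genes = np.asarray(genes, dtype=float).ravel()
    D = genes.size
    if D < 1:
        raise ValueError("need at least one boundary gene")
    if D >= L:
        raise ValueError(f"cannot place {D} distinct boundaries in [1, {L - 1}]")
    vals = np.clip(np.rint(genes).astype(int), 1, L - 1)
    used: set[int] = set()
    for v in sorted(vals):
        if v not in used:
            used.add(v)
            continue
        w = v + 1
        while w <= L - 1 and w in used:
            w += 1
        if w <= L - 1:
            used.add(w)
            continue
        w = v - 1
        while w >= 1 and w in used:
            w -= 1
        if w < 1:  # unreachable given D < L, kept as a guard
            raise ValueError("no free boundary slot during repair")
        used.add(w)
    return Partition(boundaries=tuple(int(v) for v in sorted(used)), L=L)


def _omega(W: SimilarityMatrix | np.ndarray) -> np.ndarray:
    return W.omega if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)


class FitnessEvaluator:
    """Adjacent-subspace normalized-association fitness over a fixed affinity.

    Precomputes a 2-D prefix-sum (integral image) of the affinity matrix so
    each evaluation costs O(K) block-sum lookups instead of O(L^2); the
    evolutionary loop calls this thousands of times against one matrix.
    """

    def __init__(
        self,
        W: SimilarityMatrix | np.ndarray,
        include_diagonal: bool = True,
        adjacent_only: bool = False,
    ):
        omega = _omega(W)
        if omega.ndim != 2 or omega.shape[0] != omega.shape[1]:
            raise ValueError("affinity matrix must be square")
        self.L = omega.shape[0]
        self.include_diagonal = include_diagonal
        self.adjacent_only = adjacent_only
        S = np.zeros((self.L + 1, self.L + 1))
        S[1:, 1:] = omega.cumsum(axis=0).cumsum(axis=1)
        self._S = S
        self._diag_cum = np.concatenate(([0.0], np.diag(omega).cumsum()))

    def _block(self, r0: int, r1: int, c0: int, c1: int) -> float:
        S = self._S
        return S[r1, c1] - S[r0, c1] - S[r1, c0] + S[r0, c0]

    def from_boundaries(self, boundaries: tuple[int, ...]) -> float:
        edges = (0, *boundaries, self.L)
        K = len(edges) - 1
        if K < 2:
            raise ValueError("fitness needs at least 2 subspaces")
        total = 0.0
        for k in range(K):
            s, e = edges[k], edges[k + 1]
            within = self._block(s, e, s, e)
            if not self.include_diagonal:
                within -= self._diag_cum[e] - self._diag_cum[s]
            neighbor = 0.0
            if k > 0:
                neighbor += self._block(s, e, edges[k - 1], s)
            if k < K - 1:
                neighbor += self._block(s, e, e, edges[k + 2])
            denom = neighbor if self.adjacent_only else within + neighbor
            total += within / max(denom, _DENOM_FLOOR)
        return total

    def __call__(self, partition: Partition) -> float:
        if partition.L != self.L:
            raise ValueError(
                f"partition is over {partition.L} bands but affinity matrix has {self.L}"
            )
        return self.from_boundaries(partition.boundaries)


def fitness(
    partition: Partition,
    W: SimilarityMatrix | np.ndarray,
    include_diagonal: bool = True,
    adjacent_only: bool = False,
) -> float:
    """Score a partition (larger is better).

    Default: sum over subspaces of within-affinity over within-plus-
    adjacent affinity (bounded NA form).  ``adjacent_only=True`` divides by
    the neighbor pairs alone.  The within sum runs over all ordered pairs
    including ``i == j``; end subspaces have a single neighbor, interior
    ones two.
    """
    return FitnessEvaluator(
        W, include_diagonal=include_diagonal, adjacent_only=adjacent_only
    )(partition)


def fitness_of_genes(
    genes: np.ndarray,
    L: int,
    W: SimilarityMatrix | np.ndarray,
    include_diagonal: bool = True,
    adjacent_only: bool = False,
) -> float:
    """Decode a chromosome and score the resulting partition."""
    return fitness(
        decode(genes, L), W,
        include_diagonal=include_diagonal, adjacent_only=adjacent_only,
    )


def enumerate_partitions(L: int, K: int):
    """Yield every partition of ``[0, L)`` into ``K`` contiguous subspaces.

    Exhaustive C(L-1, K-1) enumeration; the independent ground truth for
    optimizer tests on small instances.
    """
    from itertools import combinations

    for bounds in combinations(range(1, L), K - 1):
        yield Partition(boundaries=bounds, L=L)
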