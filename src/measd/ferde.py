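"""Multimodal differential evolution with fitness-Euclidean-distance-ratio niching.

FERDE keeps several optima alive in one population by two mechanisms:

* parents are drawn by roulette over FER(j, i) = (f(p_j) - f(p_w)) / ||p_j - p_i||,
  which favors individuals that are both fit and *close* to the target
  individual i (p's are personal bests, p_w the worst personal best), so
  offspring are generated within niches rather than across them;
* an offspring replaces the *nearest* existing individual, and only if
  strictly better, so distinct basins do not overwrite each other.

Mutation and crossover are standard DE: v = x_r1 + u .* (x_r2 - x_r3) with
per-dimension u ~ U(0,1), then binomial crossover against x_r1 with one
forced mutant gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_hsi import SpectralCube
from .partition import FitnessEvaluator, decode
from .similarity import SimilarityMatrix, compute_similarity, subsample_pixels

logger = logging.getLogger(__name__)

#: sentinel returned by :func:`fer` for coincident personal bests
EXCLUDED = None

_ZERO_DIST = 1e-12
_EPS_SEL = 1e-12


@dataclass
class Individual:
    genes: np.ndarray
    fitness: float
    pbest_genes: np.ndarray
    pbest_fitness: float
    _L: int = 0
    _boundaries: tuple[int, ...] | None = field(default=None, repr=False)

    @property
    def boundaries(self) -> tuple[int, ...]:
        """Decoded boundary phenotype (cached; genes are not mutated in place)."""
        if self._boundaries is None:
            self._boundaries = decode(self.genes, self._L).boundaries
        return self._boundaries


@dataclass
class Population:
    members: list[Individual]
    L: int
    generation: int = 0
    best_fitness_trace: list[float] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def best(self) -> Individual:
        return max(self.members, key=lambda m: m.fitness)

    def distinct_phenotypes(self) -> set[tuple[int, ...]]:
        return {m.boundaries for m in self.members}


@dataclass
class RunConfig:
    """Run parameters for the evolutionary search.

    Defaults follow the reference protocol: population 50, at most 300
    generations, stopping early when the best fitness has not improved for
    10 consecutive generations, local-scale neighbor order 7.
    """

    M: int = 50
    T_max: int = 300
    patience: int = 10
    seed: int = 0
    CR_mode: str = "random"  # CR ~ U(0,1) per offspring; "fixed" uses CR_value
    CR_value: float | None = None
    k_subsets: int = 3
    improvement_tol: float = 1e-12
    d_neighbor: int = 7
    sigma_mode: str = "knn"
    sigma_floor: float = 1e-12
    include_diagonal: bool = True
    adjacent_only: bool = False  # strictly-adjacent fitness denominator variant
    subsample: int | None = None  # pixel subsample size for the affinity matrix

    def __post_init__(self) -> None:
        if self.M < 4:
            raise ValueError("population size must be >= 4 (mutation needs 3 parents + target)")
        if self.T_max < 1 or self.patience < 1:
            raise ValueError("T_max and patience must be positive")
        if self.CR_mode not in ("random", "fixed"):
            raise ValueError(f"unknown CR_mode {self.CR_mode!r}")
        if self.CR_mode == "fixed":
            if self.CR_value is None or not 0.0 < self.CR_value < 1.0:
                raise ValueError("CR_mode='fixed' requires CR_value in (0, 1)")
        if self.k_subsets < 1:
            raise ValueError("k_subsets must be >= 1")


def init_population(
    L: int,
    D: int,
    M: int,
    rng: np.random.Generator | int,
    evaluator: FitnessEvaluator,
) -> Population:
    """Draw M chromosomes uniformly on ``[1, L-1]^D`` and evaluate them."""
    if M < 4:
        raise ValueError("population size must be >= 4")
    if D >= L:
        raise ValueError(f"cannot place {D} boundaries in [1, {L - 1}]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    members = []
    for _ in range(M):
        genes = rng.uniform(1.0, L - 1.0, size=D)
        f = evaluator.from_boundaries(decode(genes, L).boundaries)
        members.append(
            Individual(genes=genes, fitness=f, pbest_genes=genes.copy(), pbest_fitness=f, _L=L)
        )
    pop = Population(members=members, L=L)
    pop.best_fitness_trace.append(pop.best.fitness)
    return pop


def fer(
    pj_fitness: float, pw_fitness: float, pj: np.ndarray, pi: np.ndarray
) -> float | None:
    """Fitness-Euclidean-distance ratio of candidate j relative to target i.

    Returns :data:`EXCLUDED` when the two personal bests coincide (zero
    gene distance), in which case j carries no directional information
    about i's niche.
    """
    dist = float(np.linalg.norm(np.asarray(pj, dtype=float) - np.asarray(pi, dtype=float)))
    if dist < _ZERO_DIST:
        return EXCLUDED
    return (pj_fitness - pw_fitness) / dist


def select_parents(
    pop: Population, i: int, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Roulette-select three distinct parents for target i, FER-weighted.

    Weights are ``max(FER(j, i), 0) + eps`` over candidates with non-zero
    gene distance to i; zero-distance candidates only enter (uniformly) if
    fewer than three weighted candidates exist.  Falls back to a uniform
    draw when every weight is the epsilon floor.
    """
    M = pop.size
    if M < 4:
        raise ValueError("need at least 4 individuals to pick 3 parents plus the target")
    target = pop.members[i]
    pw_fitness = min(m.pbest_fitness for m in pop.members)
    candidates, weights, excluded = [], [], []
    for j, m in enumerate(pop.members):
        if j == i:
            continue
        score = fer(m.pbest_fitness, pw_fitness, m.pbest_genes, target.pbest_genes)
        if score is EXCLUDED:
            excluded.append(j)
        else:
            candidates.append(j)
            weights.append(max(score, 0.0) + _EPS_SEL)
    chosen: list[int] = []
    cand = list(candidates)
    w = np.array(weights, dtype=float)
    while len(chosen) < 3 and cand:
        p = w / w.sum()
        pick = int(rng.choice(len(cand), p=p))
        chosen.append(cand.pop(pick))
        w = np.delete(w, pick)
    while len(chosen) < 3:  # top up from zero-distance candidates, uniformly
        pick = int(rng.integers(len(excluded)))
        chosen.append(excluded.pop(pick))
    return chosen[0], chosen[1], chosen[2]


def mutate(
    x_r1: np.ndarray, x_r2: np.ndarray, x_r3: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """DE difference mutation with an independent U(0,1) factor per dimension."""
    x_r1, x_r2, x_r3 = (np.asarray(x, dtype=float) for x in (x_r1, x_r2, x_r3))
    if not (x_r1.shape == x_r2.shape == x_r3.shape):
        raise ValueError("parent vectors must have equal length")
    u = rng.random(x_r1.size)
    return x_r1 + u * (x_r2 - x_r3)


def crossover(
    v_p: np.ndarray, x_r1: np.ndarray, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover of mutant v_p against parent x_r1.

    Each gene takes the mutant value with probability CR; one uniformly
    chosen dimension is forced to the mutant so the offspring never
    degenerates to a copy of the parent.
    """
    v_p = np.asarray(v_p, dtype=float)
    x_r1 = np.asarray(x_r1, dtype=float)
    if v_p.shape != x_r1.shape:
        raise ValueError("mutant and parent must have equal length")
    D = v_p.size
    d_rand = int(rng.integers(D))
    take = rng.random(D) < CR
    take[d_rand] = True
    return np.where(take, v_p, x_r1)


def replace_nearest(
    pop: Population, u_genes: np.ndarray, u_fitness: float
) -> bool:
    """Replace the phenotypically nearest member if the offspring is better.

    Distance is the Euclidean distance between *decoded* boundary vectors,
    so gene vectors that round to the same partition compete directly; ties
    go to the lowest member index.  Replacement requires strictly greater
    fitness, and re-seeds the slot's personal best from the offspring.
    Returns whether a replacement happened.
    """
    if not np.isfinite(u_fitness):
        raise ValueError("offspring fitness must be finite")
    u_genes = np.asarray(u_genes, dtype=float)
    u_bounds = np.array(decode(u_genes, pop.L).boundaries, dtype=float)
    dists = [
        float(np.linalg.norm(np.array(m.boundaries, dtype=float) - u_bounds))
        for m in pop.members
    ]
    idx = int(np.argmin(dists))  # argmin takes the lowest index on ties
    if u_fitness > pop.members[idx].fitness:
        pop.members[idx] = Individual(
            genes=u_genes.copy(),
            fitness=u_fitness,
            pbest_genes=u_genes.copy(),
            pbest_fitness=u_fitness,
            _L=pop.L,
        )
        return True
    return False


def run(
    cube: SpectralCube,
    n_bands: int,
    config: RunConfig | None = None,
    W: SimilarityMatrix | np.ndarray | None = None,
) -> Population:
    """Full evolutionary search for n_bands-subspace partitions of a cube.

    Computes the band-affinity matrix once (unless supplied), then runs the
    niched DE loop until ``T_max`` generations or until the best fitness
    has not improved by more than ``improvement_tol`` for ``patience``
    consecutive generations.  All randomness flows from ``config.seed``, so
    a run is bit-reproducible.
    """
    config = config or RunConfig()
    L = cube.n_bands
    if not 2 <= n_bands <= L:
        raise ValueError(f"n_bands must be in [2, {L}], got {n_bands}")
    D = n_bands - 1
    rng = np.random.default_rng(config.seed)
    if W is None:
        sim_cube = cube
        if config.subsample is not None and config.subsample < cube.n_pixels:
            sim_cube = subsample_pixels(cube, config.subsample, seed=config.seed)
        W = compute_similarity(
            sim_cube,
            d=config.d_neighbor,
            sigma_mode=config.sigma_mode,
            sigma_floor=config.sigma_floor,
        )
    evaluator = FitnessEvaluator(
        W, include_diagonal=config.include_diagonal, adjacent_only=config.adjacent_only
    )
    pop = init_population(L, D, config.M, rng, evaluator)
    stall = 0
    for t in range(config.T_max):
        for i in range(config.M):
            r1, r2, r3 = select_parents(pop, i, rng)
            v = mutate(pop.members[r1].genes, pop.members[r2].genes, pop.members[r3].genes, rng)
            CR = float(rng.random()) if config.CR_mode == "random" else float(config.CR_value)
            u = crossover(v, pop.members[r1].genes, CR, rng)
            u_fitness = evaluator.from_boundaries(decode(u, L).boundaries)
            replace_nearest(pop, u, u_fitness)
        pop.generation = t + 1
        best = pop.best.fitness
        prev = pop.best_fitness_trace[-1]
        pop.best_fitness_trace.append(best)
        if best - prev > config.improvement_tol:
            stall = 0
        else:
            stall += 1
        if logger.isEnabledFor(logging.DEBUG):
            mean = float(np.mean([m.fitness for m in pop.members]))
            logger.debug(
                "gen %d best=%.6f mean=%.6f phenotypes=%d",
                pop.generation, best, mean, len(pop.distinct_phenotypes()),
            )
        if stall >= config.patience:
            logger.info("converged at generation %d (no improvement for %d)", t + 1, stall)
            break
    return pop
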