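"""Synthetic cubes with planted contiguous band-group structure.

Real hyperspectral cubes have a strongly ordered band axis: adjacent bands
are highly correlated, and correlation drops where the sensor crosses a
spectral regime.  The generator plants exactly that structure: the band
axis is split into contiguous groups, each group shares one random base
pixel-profile, and every band is the group's base plus i.i.d. Gaussian
noise.  Within-group band affinity is then high and between-group affinity
low, which is the structure the adjacent-subspace fitness rewards — so the
true boundaries are a known optimum any search stage can be tested against.

Labels are a deterministic function of a few informative bands (one per
group), so a downstream classifier or regressor has signal exactly where
the planted structure says it should.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_hsi import LabelData, SpectralCube
from .partition import Partition
from .similarity import SimilarityMatrix, compute_similarity


@dataclass
class SyntheticSpec:
    """Conditions for a planted block cube.

    Defaults: 30 bands in 5 equal groups, 200 pixels, reflectance-like
    amplitudes — group base profiles at scale 0.05 against within-group
    band noise 0.005 (a 10:1 separation-to-noise ratio).  The amplitude
    scale matters because the locally-scaled kernel uses *squared*
    neighbor distances and is therefore not scale-invariant; 0.05 keeps
    between-group band distances of order one for a few hundred pixels,
    the regime where the kernel resolves block structure, and is the size
    of regime-crossing reflectance steps in real spectra.
    """

    L: int = 30
    N: int = 200
    true_boundaries: tuple[int, ...] = (6, 12, 18, 24)
    within_noise: float = 0.005
    between_sep: float = 0.05
    n_classes: int = 3
    regression_coefs: np.ndarray | None = None
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2 or self.N < 1:
            raise ValueError("need L >= 2 bands and N >= 1 pixels")
        b = tuple(int(x) for x in self.true_boundaries)
        if any(not 1 <= x <= self.L - 1 for x in b) or any(
            b[i] >= b[i + 1] for i in range(len(b) - 1)
        ):
            raise ValueError(f"boundaries {b} must be strictly increasing in [1, {self.L - 1}]")
        self.true_boundaries = b
        if self.within_noise <= 0 or self.between_sep <= 0:
            raise ValueError("within_noise and between_sep must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def generate_block_cube(spec: SyntheticSpec) -> tuple[SpectralCube, Partition]:
    """Generate a cube whose bands form contiguous correlated groups.

    Each group g gets a base profile ``between_sep * z_g`` with
    ``z_g ~ N(0, I_N)``; band b in group g is ``base_g + within_noise * eps``
    with fresh ``eps ~ N(0, I_N)`` per band.  Deterministic given
    ``spec.seed``.  Returns the cube and the true partition.
    """
    rng = np.random.default_rng(spec.seed)
    truth = Partition(boundaries=spec.true_boundaries, L=spec.L)
    data = np.empty((spec.N, spec.L))
    for s, e in truth.subspaces:
        base = spec.between_sep * rng.standard_normal(spec.N)
        for b in range(s, e):
            data[:, b] = base + spec.within_noise * rng.standard_normal(spec.N)
    return SpectralCube(data), truth


def generate_mirrored_cube(spec: SyntheticSpec) -> tuple[SpectralCube, Partition]:
    """A cube that is exactly symmetric under band reversal.

    Generates a half-cube from ``spec`` and appends its band-reversed copy,
    so ``x_b == x_{2L-1-b}`` bit-for-bit.  Every partition then has a
    mirror partition with *identical* fitness, giving a landscape with (at
    least) two exactly tied optima — the ground truth for testing that the
    niched search retains multiple optima rather than collapsing to one.
    """
    half, half_truth = generate_block_cube(spec)
    data = np.concatenate([half.data, half.data[:, ::-1]], axis=1)
    L = 2 * spec.L
    # the last half-group and its mirror share a base, so the junction at
    # spec.L is interior to one group, not a boundary
    bounds = tuple(half_truth.boundaries) + tuple(
        L - b for b in reversed(half_truth.boundaries)
    )
    return SpectralCube(data), Partition(boundaries=bounds, L=L)


def _lloyd_refine(Z: np.ndarray, labels: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Refine a class assignment to a converged nearest-centroid labeling.

    Plain Lloyd iterations; at convergence each point is nearest its own
    class mean, which is the separability the labels promise downstream.
    An emptied class keeps its previous centroid.
    """
    centroids = np.stack([Z[labels == c].mean(axis=0) if np.any(labels == c)
                          else Z.mean(axis=0) for c in range(k)])
    for _ in range(max_iter):
        d = ((Z[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        new = np.argmin(d, axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for c in range(k):
            if np.any(labels == c):
                centroids[c] = Z[labels == c].mean(axis=0)
    return labels


def informative_bands(truth: Partition) -> tuple[int, ...]:
    """Middle band of each planted group — the bands labels are read from."""
    return tuple((s + e) // 2 for s, e in truth.subspaces)


def generate_labels(
    cube: SpectralCube,
    mode: str,
    spec: SyntheticSpec,
    truth: Partition | None = None,
) -> LabelData:
    """Derive per-pixel labels/targets from the informative bands.

    Classification: class = argmax of ``n_classes`` class-specific linear
    readouts of the standardized informative-band values.  The readouts are
    nearest-centroid rules: class centroids start from a seeded random
    linear-readout assignment and are refined by Lloyd iterations until the
    assignment is stable, so every pixel ends up nearest its own class
    centroid — the classes are exactly centroid-separable in the
    informative bands.  A ``label_noise`` fraction of pixels is then
    flipped to a random other class.
    Regression: target = linear combination of the informative bands (unit
    coefficients unless ``spec.regression_coefs`` is given) plus
    ``label_noise``-scaled Gaussian noise.  Deterministic given
    ``spec.seed`` (a stream independent of the cube-generation draws).
    """
    truth = truth or Partition(boundaries=spec.true_boundaries, L=spec.L)
    bands = informative_bands(truth)
    F = cube.data[:, list(bands)]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    if mode == "classification":
        mu = F.mean(axis=0)
        sd = F.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (F - mu) / sd
        R = rng.standard_normal((spec.n_classes, len(bands)))
        labels = np.argmax(Z @ R.T, axis=1)
        # refine on the raw informative bands: downstream learners see F,
        # so that is the space in which separability must hold
        labels = _lloyd_refine(F, labels, spec.n_classes)
        if spec.label_noise > 0:
            flip = rng.random(cube.n_pixels) < spec.label_noise
            labels[flip] = (labels[flip] + rng.integers(1, spec.n_classes, flip.sum())) % spec.n_classes
        return LabelData(kind="classification", values=labels)
    if mode == "regression":
        coefs = (
            np.asarray(spec.regression_coefs, dtype=float)
            if spec.regression_coefs is not None
            else np.ones(len(bands))
        )
        if coefs.shape[0] != len(bands):
            raise ValueError("regression_coefs length must match the number of groups")
        y = F @ coefs + spec.label_noise * rng.standard_normal(cube.n_pixels)
        return LabelData(kind="regression", values=y)
    raise ValueError(f"unknown label mode {mode!r}")


def planted_structure_check(
    cube: SpectralCube,
    truth: Partition,
    W: SimilarityMatrix | None = None,
    d: int = 7,
) -> bool:
    """True iff mean within-group affinity beats mean affinity across every
    planted boundary (adjacent-group pairs only)."""
    if W is None:
        d = min(d, cube.n_bands - 1)
        W = compute_similarity(cube, d=d)
    omega = W.omega
    spans = truth.subspaces
    for k in range(len(spans)):
        s, e = spans[k]
        block = omega[s:e, s:e]
        size = e - s
        if size > 1:
            within = (block.sum() - size) / (size * (size - 1))
        else:
            within = 1.0
        for adj in (k - 1, k + 1):
            if 0 <= adj < len(spans):
                a_s, a_e = spans[adj]
                across = omega[s:e, a_s:a_e].mean()
                if not within > across:
                    return False
    return True
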