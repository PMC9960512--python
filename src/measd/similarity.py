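"""Band-affinity matrix with locally scaled Gaussian kernel.

Each band is a length-N vector over pixels.  The affinity between bands i
and j is

    omega_ij = exp(-||x_i - x_j||^2 / (sigma_i sigma_j))

where sigma_i is a per-band local scale derived from the distance to the
d-th adjacent band (self-tuning spectral clustering style).  One global
matrix is computed per run and reused by every fitness evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io_hsi import SpectralCube


@dataclass
class SimilarityMatrix:
    """L x L band affinity matrix plus the local scales that produced it.

    Attributes
    ----------
    omega
        Symmetric matrix with unit diagonal, entries in (0, 1] (entries can
        underflow to 0.0 in floating point for very distant bands).
    sigma
        Length-L local scales (after flooring), all > 0.
    d
        Neighbor order used for the local scale.
    """

    omega: np.ndarray
    sigma: np.ndarray
    d: int

    @property
    def n_bands(self) -> int:
        return self.omega.shape[0]


def compute_similarity(
    cube: SpectralCube,
    d: int = 7,
    sigma_mode: str = "knn",
    sigma_floor: float = 1e-12,
    squared_sigma: bool = True,
    scale_bands: bool = False,
) -> SimilarityMatrix:
    """Compute the locally-scaled Gaussian band-affinity matrix.

    Parameters
    ----------
    cube
        Pixel-by-band matrix; bands are compared as length-N vectors.
    d
        Neighbor order for the local scale sigma_i (default 7); must lie in
        ``[1, L-1]``.
    sigma_mode
        ``knn``: sigma_i comes from the d-th *nearest* band of i by
        Euclidean distance (the local-scaling convention); ``index``: the
        band at spectral index ``i+d`` (falling back to ``i-d`` near the
        upper edge).
    sigma_floor
        Lower bound applied to each sigma_i; prevents division by zero when
        a band has an exact duplicate among its d nearest neighbors.
    squared_sigma
        If True (default) sigma_i is the *squared* distance to the chosen
        neighbor; if False, the unsquared distance.
    scale_bands
        Min-max scale each band to [0, 1] before computing distances.
    """
    X = cube.data.T  # bands as rows, shape (L, N)
    L = X.shape[0]
    if not 1 <= d <= L - 1:
        raise ValueError(f"neighbor order d={d} out of range [1, {L - 1}]")
    if scale_bands:
        mn = X.min(axis=1, keepdims=True)
        rng = X.max(axis=1, keepdims=True) - mn
        rng[rng == 0] = 1.0
        X = (X - mn) / rng
    D2 = squareform(pdist(X, metric="sqeuclidean"))
    if sigma_mode == "knn":
        # column 0 of the sorted row is the self-distance (0); the d-th
        # adjacent band is column d
        sigma = np.sort(D2, axis=1)[:, d]
    elif sigma_mode == "index":
        idx = np.arange(L) + d
        idx[idx > L - 1] = np.arange(L)[idx > L - 1] - d
        sigma = D2[np.arange(L), idx]
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    if not squared_sigma:
        sigma = np.sqrt(sigma)
    floored = sigma < sigma_floor
    if floored.all():
        warnings.warn(
            "all local scales fell below sigma_floor (near-identical bands); "
            "the affinity matrix is degenerate",
            RuntimeWarning,
        )
    sigma = np.maximum(sigma, sigma_floor)
    omega = np.exp(-D2 / np.outer(sigma, sigma))
    # exact symmetry and unit diagonal, guarding round-off
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 1.0)
    return SimilarityMatrix(omega=omega, sigma=sigma, d=d)


def subsample_pixels(cube: SpectralCube, m: int, seed: int) -> SpectralCube:
    """Draw ``m`` pixels uniformly without replacement (deterministic given seed).

    Used to bound the O(N L^2) cost of the affinity computation on large
    scenes; band-selection quality depends on band-to-band geometry, which a
    uniform pixel sample preserves in expectation.
    """
    n = cube.n_pixels
    if not 1 <= m <= n:
        raise ValueError(f"subsample size m={m} out of range [1, {n}]")
    if m == n:
        return SpectralCube(
            cube.data.copy(), wavelengths=cube.wavelengths, band_names=cube.band_names
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=m, replace=False))
    return SpectralCube(
        cube.data[idx], wavelengths=cube.wavelengths, band_names=cube.band_names
    )
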