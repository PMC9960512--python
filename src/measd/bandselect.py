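"""Representative-band extraction and the multi-subset ensemble.

From a converged population: sort individuals by fitness, keep the top k
*distinct* partitions (distinctness judged on decoded boundaries, not raw
genes), then pick one band per subspace — the band whose quantized
gray-level histogram has maximum Shannon entropy.  The k resulting band
subsets each train a predictor; predictions are combined by per-sample
majority vote (classification) or mean (regression).
"""

from __future__ import annotations

import copy
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .io_hsi import LabelData, SpectralCube
from .ferde import Population
from .partition import Partition


@dataclass
class EntropyVector:
    """Per-band Shannon entropies of min-max quantized gray histograms."""

    H: np.ndarray  # length L, in nats (log_base="e") or bits ("2")
    bins: int
    log_base: str = "e"


@dataclass(frozen=True)
class BandSubset:
    """One selected band per subspace of a source partition."""

    bands: tuple[int, ...]  # strictly increasing, one per subspace
    source_partition: Partition
    fitness: float | None = None

    def __post_init__(self) -> None:
        spans = self.source_partition.subspaces
        if len(self.bands) != len(spans):
            raise ValueError("need exactly one band per subspace")
        for b, (s, e) in zip(self.bands, spans):
            if not s <= b < e:
                raise ValueError(f"band {b} outside its subspace [{s}, {e})")


def band_entropy(cube: SpectralCube, bins: int = 256, log_base: str = "e") -> EntropyVector:
    """Shannon entropy of each band's quantized gray-level histogram.

    Each band is min-max scaled to ``[0, bins-1]`` and floored to integer
    gray levels (a constant band maps to level 0 and scores zero entropy);
    ``p(z)`` is the level's pixel frequency and ``H = -sum p log p``.
    Entropy is therefore invariant to affine rescaling of a band.  256
    levels match the 8-bit gray-image convention.
    """
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    if log_base not in ("e", "2"):
        raise ValueError("log_base must be 'e' or '2'")
    X = cube.data
    n, l = X.shape
    H = np.zeros(l)
    for i in range(l):
        band = X[:, i]
        mn, mx = band.min(), band.max()
        if mx == mn:
            continue
        levels = np.floor((band - mn) / (mx - mn) * (bins - 1)).astype(np.int64)
        np.clip(levels, 0, bins - 1, out=levels)
        counts = np.bincount(levels, minlength=1)
        p = counts[counts > 0] / n
        H[i] = -np.sum(p * np.log(p))
    if log_base == "2":
        H = H / np.log(2.0)
    return EntropyVector(H=H, bins=bins, log_base=log_base)


def representative_bands(
    partition: Partition, H: EntropyVector | np.ndarray, fitness: float | None = None
) -> BandSubset:
    """Pick the maximum-entropy band in each subspace (ties: lowest index)."""
    Hvec = H.H if isinstance(H, EntropyVector) else np.asarray(H, dtype=float)
    if Hvec.shape[0] != partition.L:
        raise ValueError(
            f"entropy vector has {Hvec.shape[0]} bands, partition covers {partition.L}"
        )
    bands = tuple(int(s + np.argmax(Hvec[s:e])) for s, e in partition.subspaces)
    return BandSubset(bands=bands, source_partition=partition, fitness=fitness)


def top_k_distinct(pop: Population, k: int, L: int | None = None) -> list[tuple[Partition, float]]:
    """Best k phenotypically distinct partitions from a final population.

    Members are sorted by fitness (descending, stable so ties keep
    population order), decoded, and deduplicated by exact boundary
    equality.  Returns ``(partition, fitness)`` pairs; warns and returns
    all available when fewer than k distinct phenotypes exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    L = L if L is not None else pop.L
    order = sorted(range(pop.size), key=lambda j: -pop.members[j].fitness)
    out: list[tuple[Partition, float]] = []
    seen: set[tuple[int, ...]] = set()
    for j in order:
        m = pop.members[j]
        if m.boundaries in seen:
            continue
        seen.add(m.boundaries)
        out.append((Partition(boundaries=m.boundaries, L=L), m.fitness))
        if len(out) == k:
            break
    if len(out) < k:
        warnings.warn(
            f"only {len(out)} distinct partitions in the population (requested {k})",
            RuntimeWarning,
        )
    return out


def select_band_subsets(
    pop: Population,
    cube: SpectralCube,
    k: int,
    bins: int = 256,
    log_base: str = "e",
) -> list[BandSubset]:
    """End-to-end subset extraction: entropy, top-k partitions, argmax bands."""
    H = band_entropy(cube, bins=bins, log_base=log_base)
    return [representative_bands(p, H, fitness=f) for p, f in top_k_distinct(pop, k)]


def integrate_predictions(
    predictions: Sequence[np.ndarray],
    task: str,
    weights: Sequence[float] | None = None,
    weighted_regression: bool = False,
) -> np.ndarray:
    """Combine per-subset predictions into one vector.

    Classification: per-sample majority vote; a tie is broken by the
    prediction of the highest-weight (highest-fitness) subset among the
    tied labels, or by subset order when no weights are given.  Regression:
    unweighted mean by default; ``weighted_regression=True`` switches to a
    fitness-weighted mean.
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to integrate")
    preds = [np.asarray(p) for p in predictions]
    n = preds[0].shape[0]
    if any(p.shape[0] != n for p in preds):
        raise ValueError("prediction vectors differ in length")
    if task == "regression":
        stack = np.stack([p.astype(float) for p in preds])
        if weighted_regression and weights is not None:
            w = np.asarray(weights, dtype=float)
            return (stack * w[:, None]).sum(axis=0) / w.sum()
        return stack.mean(axis=0)
    if task != "classification":
        raise ValueError(f"unknown task {task!r}")
    if weights is not None:
        priority = sorted(range(len(preds)), key=lambda j: -float(weights[j]))
    else:
        priority = list(range(len(preds)))
    out = np.empty(n, dtype=preds[0].dtype)
    for s in range(n):
        votes = Counter(p[s] for p in preds)
        top = max(votes.values())
        tied = {lab for lab, c in votes.items() if c == top}
        if len(tied) == 1:
            out[s] = tied.pop()
        else:
            for j in priority:
                if preds[j][s] in tied:
                    out[s] = preds[j][s]
                    break
    return out


def _fresh(learner: Any) -> Any:
    try:
        from sklearn.base import clone

        return clone(learner)
    except (TypeError, ImportError):
        return copy.deepcopy(learner)


def fit_predict_ensemble(
    cube_train: SpectralCube,
    labels_train: LabelData | np.ndarray,
    cube_test: SpectralCube,
    subsets: Sequence[BandSubset],
    learner: Any,
    task: str | None = None,
) -> np.ndarray:
    """Train one fresh learner per band subset and integrate the predictions.

    The learner need only expose ``fit(X, y)`` and ``predict(X)``;
    sklearn estimators are cloned, anything else deep-copied, so subsets
    never share fitted state.
    """
    if len(subsets) == 0:
        raise ValueError("no band subsets supplied")
    if isinstance(labels_train, LabelData):
        y = labels_train.values
        task = task or labels_train.kind
    else:
        y = np.asarray(labels_train)
        if task is None:
            task = "classification" if np.issubdtype(y.dtype, np.integer) else "regression"
    preds = []
    for s in subsets:
        model = _fresh(learner)
        model.fit(cube_train.data[:, list(s.bands)], y)
        preds.append(np.asarray(model.predict(cube_test.data[:, list(s.bands)])))
    weights = None
    if all(s.fitness is not None for s in subsets):
        weights = [float(s.fitness) for s in subsets]
    return integrate_predictions(preds, task=task, weights=weights)


def classification_report(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, Any]:
    """Overall accuracy (OA), average per-class accuracy (AA), per-class rates.

    OA is the fraction of all samples classified correctly; AA averages the
    per-class recall so small classes weigh equally.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    oa = float(np.mean(y_true == y_pred))
    per_class = {}
    for c in np.unique(y_true):
        mask = y_true == c
        per_class[int(c)] = float(np.mean(y_pred[mask] == c))
    aa = float(np.mean(list(per_class.values())))
    return {"OA": oa, "AA": aa, "per_class": per_class}


def regression_report(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Mean squared error and R^2 between targets and predictions."""
    from sklearn.metrics import mean_squared_error, r2_score

    return {
        "MSE": float(mean_squared_error(y_true, y_pred)),
        "R2": float(r2_score(y_true, y_pred)),
    }
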