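import numpy as np
import pytest

from measd.bandselect import (
    BandSubset,
    band_entropy,
    classification_report,
    fit_predict_ensemble,
    integrate_predictions,
    regression_report,
    representative_bands,
    select_band_subsets,
    top_k_distinct,
)
from measd.ferde import Individual, Population
from measd.io_hsi import SpectralCube
from measd.partition import Partition


def entropy_oracle(counts):
    n = sum(counts)
    return -sum((c / n) * np.log(c / n) for c in counts if c > 0)


class TestBandEntropy:
    def test_constant_band_has_zero_entropy(self):
        data = np.column_stack([np.full(8, 3.7), np.arange(8.0)])
        H = band_entropy(SpectralCube(data), bins=16)
        assert H.H[0] == 0.0

    def test_two_equiprobable_levels_give_ln2(self):
        band = np.array([0.0, 1.0] * 4)
        data = np.column_stack([band, np.arange(8.0)])
        H = band_entropy(SpectralCube(data), bins=256)
        assert H.H[0] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_histogram_oracle_counts_4_2_1_1(self):
        # 8 pixels quantizing to levels with counts {4, 2, 1, 1}
        band = np.array([0.0, 0.0, 0.0, 0.0, 0.4, 0.4, 0.7, 1.0])
        data = np.column_stack([band, np.zeros(8)])
        H = band_entropy(SpectralCube(data), bins=11)  # levels 0, 4, 7, 10
        assert H.H[0] == pytest.approx(entropy_oracle([4, 2, 1, 1]), abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        data = rng.random((50, 3))
        scaled = SpectralCube(data * 7.3 - 2.1)
        np.testing.assert_allclose(
            band_entropy(SpectralCube(data)).H, band_entropy(scaled).H, atol=1e-12
        )

    def test_bounds_and_base2(self, rng):
        data = rng.random((100, 5))
        H = band_entropy(SpectralCube(data), bins=32)
        assert np.all(H.H >= 0) and np.all(H.H <= np.log(32) + 1e-12)
        H2 = band_entropy(SpectralCube(data), bins=32, log_base="2")
        np.testing.assert_allclose(H2.H, H.H / np.log(2.0), atol=1e-12)

    def test_too_few_bins(self, toy_cube):
        with pytest.raises(ValueError):
            band_entropy(toy_cube, bins=1)


class TestRepresentativeBands:
    def test_single_band_subspaces_forced(self):
        p = Partition(boundaries=(1, 2, 3), L=4)
        s = representative_bands(p, np.array([0.5, 0.1, 0.9, 0.2]))
        assert s.bands == (0, 1, 2, 3)

    def test_argmax_per_subspace(self):
        p = Partition(boundaries=(2,), L=4)
        s = representative_bands(p, np.array([0.0, 1.0, 0.0, 2.0]))
        assert s.bands == (1, 3)

    def test_tie_takes_lower_index(self):
        p = Partition(boundaries=(2,), L=4)
        s = representative_bands(p, np.array([1.0, 1.0, 0.0, 0.0]))
        assert s.bands == (0, 2)

    def test_one_band_per_subspace_never_adjacent(self, rng):
        # structural anti-redundancy: subspaces of length >= 2 can never
        # contribute spectrally adjacent picks
        for _ in range(20):
            H = rng.random(12)
            p = Partition(boundaries=(3, 6, 9), L=12)
            s = representative_bands(p, H)
            assert len(s.bands) == p.K
            for b, (lo, hi) in zip(s.bands, p.subspaces):
                assert lo <= b < hi

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            representative_bands(Partition(boundaries=(2,), L=4), np.zeros(6))


def make_pop(bound_rows, fitnesses, L):
    members = [
        Individual(
            genes=np.array(b, dtype=float), fitness=f,
            pbest_genes=np.array(b, dtype=float), pbest_fitness=f, _L=L,
        )
        for b, f in zip(bound_rows, fitnesses)
    ]
    return Population(members=members, L=L)


class TestTopKDistinct:
    def test_identical_phenotypes_collapse_with_warning(self):
        pop = make_pop([[3.0], [3.2], [2.8]], [5.0, 4.0, 3.0], L=6)
        with pytest.warns(RuntimeWarning, match="distinct"):
            out = top_k_distinct(pop, 3)
        assert len(out) == 1
        assert out[0][0].boundaries == (3,)

    def test_sort_then_dedupe(self):
        pop = make_pop([[2.0], [4.0], [2.2], [3.0]], [5.0, 5.0, 4.0, 4.0], L=6)
        out = top_k_distinct(pop, 3)
        assert [p.boundaries for p, _ in out] == [(2,), (4,), (3,)]
        assert [f for _, f in out] == [5.0, 5.0, 4.0]

    def test_k1_returns_argmax_phenotype(self):
        pop = make_pop([[2.0], [4.0]], [1.0, 9.0], L=6)
        pop.members += make_pop([[3.0], [5.0]], [0.5, 0.2], L=6).members
        out = top_k_distinct(pop, 1)
        assert len(out) == 1
        assert out[0][0].boundaries == (4,)

    def test_invalid_k(self):
        pop = make_pop([[2.0]], [1.0], L=6)
        with pytest.raises(ValueError):
            top_k_distinct(pop, 0)


class TestIntegratePredictions:
    def test_majority_vote(self):
        preds = [np.array(["A", "A"]), np.array(["A", "A"]), np.array(["B", "B"])]
        out = integrate_predictions(preds, task="classification")
        assert list(out) == ["A", "A"]

    def test_regression_mean(self):
        preds = [np.array([1.0]), np.array([2.0]), np.array([3.0])]
        assert integrate_predictions(preds, task="regression")[0] == pytest.approx(2.0)

    def test_tie_broken_by_higher_fitness_subset(self):
        preds = [np.array(["A"]), np.array(["B"])]
        out = integrate_predictions(preds, task="classification", weights=[1.0, 2.0])
        assert out[0] == "B"
        out = integrate_predictions(preds, task="classification", weights=[2.0, 1.0])
        assert out[0] == "A"

    def test_weighted_regression_mean(self):
        preds = [np.array([0.0]), np.array([4.0])]
        out = integrate_predictions(
            preds, task="regression", weights=[1.0, 3.0], weighted_regression=True
        )
        assert out[0] == pytest.approx(3.0)

    def test_single_vector_is_identity(self):
        pred = np.array([1, 2, 3])
        assert np.array_equal(
            integrate_predictions([pred], task="classification"), pred
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            integrate_predictions([], task="classification")
        with pytest.raises(ValueError):
            integrate_predictions(
                [np.array([1]), np.array([1, 2])], task="classification"
            )


class _MeanThresholdLearner:
    """Deterministic toy classifier: nearest class centroid."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        self.centroids_ = np.stack([X[y == c].mean(axis=0) for c in self.classes_])
        return self

    def predict(self, X):
        d = ((X[:, None, :] - self.centroids_[None]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d, axis=1)]


class TestFitPredictEnsemble:
    def _subsets(self, bands_list, fitnesses, L):
        out = []
        for bands, f in zip(bands_list, fitnesses):
            bounds = tuple(
                (bands[i] + bands[i + 1] + 1) // 2 for i in range(len(bands) - 1)
            )
            out.append(
                BandSubset(bands=tuple(bands), fitness=f,
                           source_partition=Partition(boundaries=bounds, L=L))
            )
        return out

    def test_duplicated_subsets_match_single(self, rng):
        X = rng.random((40, 6))
        y = (X[:, 1] > 0.5).astype(int)
        cube = SpectralCube(X)
        (sub,) = self._subsets([[1, 4]], [1.0], 6)
        single = fit_predict_ensemble(cube, y, cube, [sub], _MeanThresholdLearner())
        triple = fit_predict_ensemble(cube, y, cube, [sub] * 3, _MeanThresholdLearner())
        assert np.array_equal(single, triple)

    def test_complementary_errors_fixed_by_vote(self):
        # two feature pairs err on disjoint sample blocks; a third is clean.
        # majority vote must be at least as accurate as any single subset.
        rng = np.random.default_rng(8)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = np.zeros((n, 6))
        X[:, 0] = y + 0.05 * rng.standard_normal(n)
        X[:10, 0] = 1 - y[:10]  # subset A errs on the first block
        X[:, 2] = y + 0.05 * rng.standard_normal(n)
        X[20:30, 2] = 1 - y[20:30]  # subset B errs on a different block
        X[:, 4] = y + 0.05 * rng.standard_normal(n)
        X[40:50, 4] = 1 - y[40:50]  # subset C errs on a third block
        X[:, 1] = X[:, 3] = X[:, 5] = 0.0
        cube = SpectralCube(X)
        subsets = self._subsets([[0, 1], [2, 3], [4, 5]], [3.0, 2.0, 1.0], 6)
        singles = [
            np.mean(
                fit_predict_ensemble(cube, y, cube, [s], _MeanThresholdLearner()) == y
            )
            for s in subsets
        ]
        ensemble = np.mean(
            fit_predict_ensemble(cube, y, cube, subsets, _MeanThresholdLearner()) == y
        )
        assert ensemble >= max(singles)
        assert ensemble == 1.0  # errors are disjoint, vote fixes all of them

    def test_sklearn_estimators_are_cloned(self, rng):
        from sklearn.neighbors import NearestCentroid

        X = rng.random((30, 6))
        y = (X[:, 0] > 0.5).astype(int)
        cube = SpectralCube(X)
        learner = NearestCentroid()
        subsets = self._subsets([[0, 3], [0, 5]], [2.0, 1.0], 6)
        preds = fit_predict_ensemble(cube, y, cube, subsets, learner)
        assert preds.shape == (30,)
        assert not hasattr(learner, "centroids_")  # original never fitted


class TestReports:
    def test_classification_oa_aa(self):
        y = np.array([0, 0, 0, 1])
        p = np.array([0, 0, 1, 1])
        rep = classification_report(y, p)
        assert rep["OA"] == pytest.approx(0.75)
        # per-class rates 2/3 and 1/1 average differently from OA
        assert rep["AA"] == pytest.approx((2 / 3 + 1.0) / 2)

    def test_regression_mse_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = regression_report(y, y)
        assert rep["MSE"] == 0.0 and rep["R2"] == 1.0


class TestSelectBandSubsets:
    def test_end_to_end_bands_inside_subspaces(self, planted_small):
        cube, truth, W = planted_small
        from measd.ferde import RunConfig, run

        pop = run(cube, 3, RunConfig(M=12, T_max=40, seed=1), W=W)
        subsets = select_band_subsets(pop, cube, k=2)
        assert 1 <= len(subsets) <= 2
        for s in subsets:
            for b, (lo, hi) in zip(s.bands, s.source_partition.subspaces):
                assert lo <= b < hi
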