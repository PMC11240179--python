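"""Tests for the kNN-based corpus statistics against exhaustive oracles."""

import numpy as np
import pytest

from litatlas.embed import Embedding2D
from litatlas.metrics import (
    chance_level_accuracy,
    isolatedness,
    knn_label_accuracy,
    knn_overlap_series,
    knn_recall,
    knn_year_rmse,
    region_flag_fraction,
)
from litatlas.synthetic import SyntheticConfig, generate_vector_mixture

from _oracles import naive_accuracy, naive_isolatedness, naive_recall, naive_year_rmse
from conftest import make_topics


class TestAccuracy:
    def test_equals_brute_force_oracle(self, mixture200):
        vs, labels, _ = mixture200
        test_idx = np.random.default_rng(0).choice(200, 40, replace=False)
        got = knn_label_accuracy(vs, labels, k=5, test_idx=test_idx).value
        assert got == naive_accuracy(vs.X, labels, test_idx, 5)

    def test_perfect_separation_gives_100(self):
        cfg = SyntheticConfig(n_papers=400, topics=make_topics(3),
                              cluster_separation=10.0, dim=20, seed=1)
        vs, labels = generate_vector_mixture(cfg)
        assert knn_label_accuracy(vs, labels, k=10, test_size=100, seed=0).value == 100.0

    def test_zero_separation_matches_chance(self):
        cfg = SyntheticConfig(n_papers=3000, topics=make_topics(4),
                              cluster_separation=0.0, dim=20, seed=2)
        vs, labels = generate_vector_mixture(cfg)
        acc = knn_label_accuracy(vs, labels, k=10, test_size=600, seed=0).value
        chance = chance_level_accuracy(labels, test_size=600, seed=0).value
        mc = 100 * 3 * np.sqrt(0.25 * 0.75 / 600)  # ~3 sd Monte-Carlo band
        assert abs(acc - chance) <= 2 * mc

    def test_unlabeled_points_excluded(self, mixture200):
        vs, labels, _ = mixture200
        labels = labels.astype(object)
        labels[::2] = None  # half unlabeled
        rep = knn_label_accuracy(vs, labels, k=5, test_size=30, seed=0)
        assert rep.n_train + rep.n_test == (labels != None).sum()

    def test_too_large_test_size_rejected(self, mixture200):
        vs, labels, _ = mixture200
        with pytest.raises(ValueError):
            knn_label_accuracy(vs, labels, test_size=500, seed=0)


class TestChance:
    def test_single_label_is_certain(self):
        labels = np.array(["only"] * 50, dtype=object)
        assert chance_level_accuracy(labels, test_size=20, seed=0).value == 100.0

    def test_two_balanced_labels_near_half(self):
        rng = np.random.default_rng(3)
        labels = rng.permutation(np.array(["a"] * 5000 + ["b"] * 5000, dtype=object))
        acc = chance_level_accuracy(labels, test_size=4000, seed=0).value
        assert abs(acc - 50.0) <= 100 * 3 * np.sqrt(0.25 / 4000)

    def test_matches_sum_p_squared(self):
        """Stratified guessing converges to sum(p^2)."""
        rng = np.random.default_rng(4)
        labels = rng.choice(["a", "b", "c"], p=[0.6, 0.3, 0.1], size=20000).astype(object)
        acc = chance_level_accuracy(labels, test_size=8000, seed=1).value
        p = np.array([np.mean(labels == lab) for lab in ("a", "b", "c")])
        expected = 100 * float((p ** 2).sum())
        assert abs(acc - expected) <= 100 * 3 * np.sqrt(0.5 * 0.5 / 8000)


class TestYearRmse:
    def test_equals_brute_force_oracle(self, mixture200):
        vs, _, years = mixture200
        test_idx = np.random.default_rng(1).choice(200, 40, replace=False)
        got = knn_year_rmse(vs, years, k=5, test_idx=test_idx).value
        assert got == pytest.approx(naive_year_rmse(vs.X, years, test_idx, 5), abs=1e-12)

    def test_constant_years_zero_error(self, mixture200):
        vs, _, _ = mixture200
        years = np.full(200, 2000.0)
        assert knn_year_rmse(vs, years, k=5, test_size=40, seed=0).value == 0.0

    def test_knn_closed_form_sigma(self):
        """Well-separated clusters: RMSE ~ sigma * sqrt(1 + 1/k)."""
        sigma, k = 4.0, 10
        cfg = SyntheticConfig(n_papers=6000, topics=make_topics(4),
                              cluster_separation=20.0, dim=10, seed=5)
        vs, labels = generate_vector_mixture(cfg)
        centers = {t: 1960 + 25 * i for i, t in enumerate(sorted(set(labels)))}
        rng = np.random.default_rng(6)
        years = np.array([centers[t] for t in labels]) + rng.normal(0, sigma, 6000)
        got = knn_year_rmse(vs, years, k=k, test_size=1500, seed=0).value
        assert got == pytest.approx(sigma * np.sqrt(1 + 1 / k), rel=0.10)

    def test_chance_closed_form_population_sigma(self):
        rng = np.random.default_rng(7)
        years = rng.normal(2000, 12.0, 6000)
        X = rng.standard_normal((6000, 5))
        got = knn_year_rmse(X, years, k=10, test_size=1500, seed=0, mode="chance").value
        assert got == pytest.approx(years.std() * np.sqrt(1 + 1 / 10), rel=0.10)


class TestRecall:
    def test_equals_brute_force_oracle(self, mixture200):
        vs, _, _ = mixture200
        low = Embedding2D(ids=vs.ids, Y=vs.X[:, :2].copy())
        subset = np.random.default_rng(2).choice(200, 50, replace=False)
        got = knn_recall(vs, low, k=5, subset_idx=subset).value
        assert got == pytest.approx(naive_recall(vs.X, low.Y, subset, 5), abs=1e-12)

    def test_identity_embedding_is_100(self, mixture200):
        vs, _, _ = mixture200
        assert knn_recall(vs, vs, k=10, subset_size=200, seed=0).value == 100.0

    def test_random_coordinates_hypergeometric_mean(self):
        n, k = 2000, 10
        rng = np.random.default_rng(8)
        X = rng.standard_normal((n, 10))
        ids = np.arange(n)
        from litatlas.vectorize import VectorSet
        high = VectorSet(ids=ids, X=X)
        low = Embedding2D(ids=ids, Y=rng.standard_normal((n, 2)))
        got = knn_recall(high, low, k=k, subset_size=1000, seed=0).value
        expected = 100 * k / (n - 1)
        mc = 100 * 3.5 * np.sqrt(0.005 * 0.995 / k / 1000)
        assert abs(got - expected) <= mc

    def test_mismatched_ids_rejected(self, mixture200):
        vs, _, _ = mixture200
        low = Embedding2D(ids=np.arange(1, 201), Y=vs.X[:, :2].copy())
        with pytest.raises(ValueError):
            knn_recall(vs, low, k=5)


class TestIsolatedness:
    def test_equals_brute_force_oracle(self, mixture200):
        vs, labels, _ = mixture200
        mask = labels == "topic0"
        subset = np.flatnonzero(mask)[:40]
        got = isolatedness(vs, mask, k=5, subset_idx=subset).value
        assert got == pytest.approx(naive_isolatedness(vs.X, mask, subset, 5), abs=1e-12)

    def test_whole_corpus_is_100(self, mixture200):
        vs, _, _ = mixture200
        mask = np.ones(200, dtype=bool)
        assert isolatedness(vs, mask, k=10, subset_size=100, seed=0).value == 100.0

    def test_tight_cluster_above_99(self):
        cfg = SyntheticConfig(n_papers=3000, topics=make_topics(3),
                              cluster_separation=10.0, dim=50, seed=9)
        vs, labels = generate_vector_mixture(cfg)
        got = isolatedness(vs, labels == "topic1", k=10, subset_size=500, seed=0).value
        assert got >= 99.0

    def test_random_mask_mixes_uniformly(self):
        n = 4000
        rng = np.random.default_rng(10)
        X = rng.standard_normal((n, 10))
        mask = rng.random(n) < 0.3
        got = isolatedness(X, mask, k=10, subset_size=600, seed=0).value
        p0 = 100 * (mask.sum() - 1) / (n - 1)
        half = 100 * 2.576 * np.sqrt(0.3 * 0.7 / (600 * 10))
        assert abs(got - p0) <= 2 * half  # neighbor sharing inflates variance

    def test_small_corpus_rejected(self, mixture200):
        vs, _, _ = mixture200
        mask = np.zeros(200, dtype=bool)
        mask[:5] = True
        with pytest.raises(ValueError):
            isolatedness(vs, mask, k=10)

    def test_monotone_in_separation(self):
        values = []
        for sep in (0.0, 4.0, 10.0):
            cfg = SyntheticConfig(n_papers=1500, topics=make_topics(3),
                                  cluster_separation=sep, dim=20, seed=11)
            vs, labels = generate_vector_mixture(cfg)
            values.append(isolatedness(vs, labels == "topic0", k=10,
                                       subset_size=300, seed=0).value)
        assert values[0] <= values[1] <= values[2]


class TestOverlapSeries:
    def _drift_data(self, n=4000, seed=12):
        """Source cluster drifts toward the target cluster over the years."""
        rng = np.random.default_rng(seed)
        years = rng.integers(2000, 2020, n)
        src = rng.random(n) < 0.5
        X = np.zeros((n, 5))
        X[~src, 0] = 12.0  # target sits at distance 12
        t = (years - 2000) / 19
        X[src, 0] = 12.0 * t[src] * 0.9
        X += rng.standard_normal((n, 5))
        return X, src, ~src, years

    def test_absent_target_all_zero(self, mixture200):
        vs, labels, years = mixture200
        series = knn_overlap_series(vs, labels == "topic0",
                                    np.zeros(200, dtype=bool), years, k=5,
                                    per_year_cap=10, seed=0)
        assert (series["overlap"] == 0).all()

    def test_monotone_drift_correlates_with_year(self):
        from scipy.stats import spearmanr

        X, src, tgt, years = self._drift_data()
        series = knn_overlap_series(X, src, tgt, years, k=10, per_year_cap=100, seed=0)
        rho = spearmanr(series["year"], series["overlap"]).statistic
        assert rho > 0.8

    def test_per_year_cap_enforced(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((3000, 4))
        years = np.full(3000, 2005)
        src = np.ones(3000, dtype=bool)
        series = knn_overlap_series(X, src, src, years, k=5, per_year_cap=500, seed=0)
        assert series["n_sampled"].tolist() == [500]

    def test_empty_source_rejected(self):
        X = np.zeros((20, 2))
        with pytest.raises(ValueError):
            knn_overlap_series(X, np.zeros(20, dtype=bool),
                               np.ones(20, dtype=bool), np.full(20, 2000))


class TestRegionFraction:
    def test_printed_style_counts(self):
        """A 422-point region with 45 flags reports fraction 45/422."""
        rng = np.random.default_rng(14)
        Y = np.vstack([rng.uniform(0, 1, (422, 2)), rng.uniform(5, 6, (100, 2))])
        flags = np.zeros(522, dtype=bool)
        flags[:45] = True
        emb = Embedding2D(ids=np.arange(522), Y=Y)
        flagged, total, frac = region_flag_fraction(emb, flags, (0, 1, 0, 1))
        assert (flagged, total) == (45, 422)
        assert frac == pytest.approx(45 / 422)

    def test_all_flagged_saturates(self):
        Y = np.random.default_rng(15).uniform(0, 1, (50, 2))
        emb = Embedding2D(ids=np.arange(50), Y=Y)
        assert region_flag_fraction(emb, np.ones(50, dtype=bool), (0, 1, 0, 1))[2] == 1.0

    def test_random_flags_near_rate(self):
        rng = np.random.default_rng(16)
        Y = rng.uniform(0, 1, (5000, 2))
        flags = rng.random(5000) < 0.2
        emb = Embedding2D(ids=np.arange(5000), Y=Y)
        _, total, frac = region_flag_fraction(emb, flags, (0, 1, 0, 1))
        assert total == 5000
        assert abs(frac - 0.2) <= 2.576 * np.sqrt(0.2 * 0.8 / 5000)

    def test_polygon_region_boundary_inclusive(self):
        Y = np.array([[0.0, 0.0], [0.5, 0.5], [2.0, 2.0]])
        emb = Embedding2D(ids=np.arange(3), Y=Y)
        poly = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        flagged, total, _ = region_flag_fraction(emb, np.array([True, False, True]), poly)
        assert total == 2 and flagged == 1  # corner point (0,0) counted

    def test_empty_region_rejected(self):
        emb = Embedding2D(ids=np.arange(2), Y=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            region_flag_fraction(emb, np.zeros(2, dtype=bool), (5, 6, 5, 6))


def test_statistics_permutation_invariant(mixture200):
    """Full-corpus statistics are exactly invariant under input permutation."""
    vs, labels, years = mixture200
    rng = np.random.default_rng(17)
    perm = rng.permutation(200)
    mask = labels == "topic0"
    subset = np.flatnonzero(mask)
    iso_a = isolatedness(vs.X, mask, k=5, subset_idx=subset).value
    inv = np.empty(200, dtype=int)
    inv[perm] = np.arange(200)
    iso_b = isolatedness(vs.X[perm], mask[perm], k=5, subset_idx=inv[subset]).value
    assert iso_a == pytest.approx(iso_b, abs=1e-12)
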