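"""PCA reduction, silhouette criterion, k-means selection, label maps."""

import numpy as np
import pytest

from saxseg.cluster import (
    fit_pca,
    knee_index,
    labels_to_map,
    mean_silhouette,
    select_m,
    select_n_and_fit,
)
from saxseg.scattering_io import ScanGrid


def brute_force_silhouette(X, labels):
    """O(r^2) textbook silhouette, independent of the vectorized path."""
    X = np.asarray(X, float)
    r = X.shape[0]
    vals = []
    for i in range(r):
        same = [j for j in range(r) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(r) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        denom = max(a, b)
        vals.append(0.0 if denom == 0 else (b - a) / denom)
    return float(np.mean(vals))


class TestFitPCA:
    def test_exact_planar_data_needs_two_components(self, rng):
        basis = rng.normal(size=(2, 10))
        coeff = rng.normal(size=(200, 2))
        model = fit_pca(coeff @ basis)
        cum = np.cumsum(model.explained_ratio)
        assert cum[1] == pytest.approx(1.0, abs=1e-9)
        assert model.m == 2

    def test_isotropic_noise_spreads_variance_evenly(self):
        rng = np.random.default_rng(77)
        model = fit_pca(rng.normal(size=(10_000, 5)))
        assert np.allclose(model.explained_ratio, 0.2, atol=0.02)

    def test_repeated_single_row_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_pca(np.tile([1.0, 2.0, 3.0], (5, 1)))

    def test_scores_pairwise_uncorrelated(self, rng):
        X = rng.normal(size=(300, 6)) @ rng.normal(size=(6, 6))
        model = fit_pca(X)
        corr = np.corrcoef(model.scores, rowvar=False)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.all(np.abs(off) < 1e-6)

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(50, 8))
        model = fit_pca(X)
        recon = model.scores @ model.components + model.mean
        assert np.sqrt(np.mean((recon - X) ** 2)) < 1e-8


class TestSelectM:
    @pytest.mark.parametrize(
        "ratios, expected",
        [
            ((0.6, 0.36, 0.04), 2),
            ((1.0,), 1),
            (tuple([0.1] * 10), 10),
        ],
    )
    def test_threshold_rule(self, ratios, expected):
        assert select_m(np.array(ratios), 0.95) == expected

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            select_m(np.array([0.5, 0.5]), 1.5)

    def test_knee_finds_the_bend(self):
        # sharp elbow after the second component
        ratio = np.array([0.55, 0.40, 0.02, 0.02, 0.01])
        assert knee_index(ratio) == 2


class TestMeanSilhouette:
    def test_far_separated_tight_clusters_approach_one(self, rng):
        a = rng.normal(scale=1e-4, size=(20, 2))
        b = rng.normal(scale=1e-4, size=(20, 2)) + 100.0
        X = np.vstack([a, b])
        labels = np.array([0] * 20 + [1] * 20)
        assert mean_silhouette(X, labels) > 0.999

    def test_identical_points_score_zero(self):
        X = np.zeros((10, 3))
        labels = np.array([0, 1] * 5)
        assert mean_silhouette(X, labels) == 0.0

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="2 clusters"):
            mean_silhouette(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))

    def test_matches_brute_force_oracle(self, rng):
        X = rng.normal(size=(12, 2))
        labels = rng.integers(0, 3, size=12)
        while len(set(labels.tolist())) < 3:
            labels = rng.integers(0, 3, size=12)
        assert mean_silhouette(X, labels) == pytest.approx(
            brute_force_silhouette(X, labels), abs=1e-12
        )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import silhouette_score

        X = rng.normal(size=(80, 3))
        labels = rng.integers(0, 4, size=80)
        assert mean_silhouette(X, labels) == pytest.approx(
            silhouette_score(X, labels), abs=1e-10
        )

    def test_invariant_under_label_permutation(self, rng):
        X = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, size=30)
        while len(set(labels.tolist())) < 3:
            labels = rng.integers(0, 3, size=30)
        permuted = np.array([(l + 1) % 3 for l in labels])
        assert mean_silhouette(X, labels) == pytest.approx(
            mean_silhouette(X, permuted), abs=1e-12
        )


class TestSelectNAndFit:
    def test_recovers_four_separated_clouds(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        X = np.vstack([c + rng.normal(scale=0.3, size=(25, 2)) for c in centers])
        model = select_n_and_fit(X, (2, 8), seed=1)
        assert model.n == 4
        # partition matches cloud membership up to label bijection
        truth = np.repeat(np.arange(4), 25)
        pairs = {(t, p) for t, p in zip(truth, model.labels)}
        assert len(pairs) == 4

    def test_line_points_prefer_two_clusters(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        # exhaustive-partition oracle for k=2 on 4 points confirms the
        # best 2-split is {0,1}|{10,11} with centroids 0.5 and 10.5
        model = select_n_and_fit(X, (2, 3), seed=0, restarts=10)
        assert model.n == 2
        assert sorted(model.centroids.ravel().tolist()) == [0.5, 10.5]

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(60, 3))
        m1 = select_n_and_fit(X, (2, 5), seed=9)
        m2 = select_n_and_fit(X, (2, 5), seed=9)
        assert np.array_equal(m1.labels, m2.labels)
        assert m1.n == m2.n

    def test_kmeans_objective_nonincreasing_over_iterations(self, rng):
        from sklearn.cluster import KMeans

        X = rng.normal(size=(200, 2))
        inertias = []
        for max_iter in range(1, 8):
            km = KMeans(
                n_clusters=3, init="k-means++", n_init=1, max_iter=max_iter,
                random_state=0, algorithm="lloyd",
            ).fit(X)
            inertias.append(km.inertia_)
        assert all(b <= a + 1e-9 for a, b in zip(inertias, inertias[1:]))


class TestLabelsToMap:
    def test_row_major_placement(self):
        lm = labels_to_map([1, 1, 2, 2], ScanGrid(2, 2))
        assert lm.labels.tolist() == [[1, 1], [2, 2]]

    def test_snake_reverses_odd_rows(self):
        lm = labels_to_map([1, 2, 3, 4], ScanGrid(2, 2, raster="snake"))
        assert lm.labels.tolist() == [[1, 2], [4, 3]]

    def test_excluded_pixel_becomes_zero(self):
        lm = labels_to_map([1, 1, 2], ScanGrid(2, 2), excluded=[1])
        assert (lm.labels == 0).sum() == 1
        assert lm.labels[0, 1] == 0

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid pixels"):
            labels_to_map([1, 2], ScanGrid(2, 2))
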