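"""Dimensionality reduction and cluster-number selection.

The sparse feature matrix M2 is reduced by PCA to m principal-component
scores; m is the smallest component count whose cumulative explained
variance reaches a threshold (default 95%), with the geometric knee of
the L-curve reported as a diagnostic.  The scores are then classified by
k-means, and the number of clusters n is chosen over a candidate range
(default 2..8) as the value maximizing the mean silhouette, computed
with the Euclidean metric on the PC scores.  Ties go to the smaller n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .scattering_io import LabelMap, ScanGrid, flat_to_grid_index

logger = logging.getLogger(__name__)

__all__ = [
    "PCAModel",
    "ClusterModel",
    "fit_pca",
    "select_m",
    "knee_index",
    "mean_silhouette",
    "select_n_and_fit",
    "labels_to_map",
]


@dataclass
class PCAModel:
    """PCA of the feature matrix with a selected component count m."""

    components: np.ndarray  # (n_components, d) loadings
    scores: np.ndarray  # (r, n_components)
    explained_ratio: np.ndarray  # fractions, nonincreasing
    mean: np.ndarray  # (d,) column means removed before the fit
    m: int  # selected component count
    knee: int  # L-curve knee diagnostic (1-based component index)

    @property
    def selected_scores(self) -> np.ndarray:
        """Scores truncated to the selected m components."""
        return self.scores[:, : self.m]


def fit_pca(values: np.ndarray, variance_threshold: float = 0.95) -> PCAModel:
    """Fit a full PCA to M2 (columns mean-centered internally).

    Components are ordered by decreasing explained variance and the
    scores of distinct components are uncorrelated by construction.
    ``m`` is chosen by :func:`select_m`; the L-curve knee is attached as
    a diagnostic.  Raises on rank-0 input (all rows identical), which
    carries no variance to decompose.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    r, d = X.shape
    if r < 2 or d < 1:
        raise ValueError("PCA needs at least 2 rows and 1 column")
    if not np.any(np.std(X, axis=0) > 0):
        raise ValueError("input has zero variance (all rows identical)")
    pca = PCA(n_components=min(r, d), svd_solver="full")
    scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    m = select_m(ratio, variance_threshold)
    knee = knee_index(ratio)
    if knee != m:
        logger.info(
            "L-curve knee at %d components differs from the %g-variance "
            "choice m=%d; the threshold rule is used",
            knee,
            variance_threshold,
            m,
        )
    return PCAModel(
        components=pca.components_,
        scores=scores,
        explained_ratio=ratio,
        mean=pca.mean_,
        m=m,
        knee=knee,
    )


def select_m(explained_ratio: np.ndarray, variance_threshold: float = 0.95) -> int:
    """Smallest m whose cumulative explained variance reaches the threshold."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance threshold must lie in (0, 1]")
    ratio = np.asarray(explained_ratio, dtype=float)
    cum = np.cumsum(ratio)
    hits = np.flatnonzero(cum >= variance_threshold - 1e-12)
    if hits.size == 0:
        return ratio.size
    return int(hits[0]) + 1


def knee_index(explained_ratio: np.ndarray) -> int:
    """Geometric knee of the L-curve: the point of maximum distance to the
    chord joining the first and last points of the cumulative-variance
    curve.  Returned 1-based; purely diagnostic."""
    cum = np.cumsum(np.asarray(explained_ratio, dtype=float))
    k = cum.size
    if k == 1:
        return 1
    x = np.arange(1, k + 1, dtype=float)
    p0 = np.array([x[0], cum[0]])
    p1 = np.array([x[-1], cum[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 1
    pts = np.column_stack([x, cum]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    return int(np.argmax(dist)) + 1


def mean_silhouette(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over all points, Euclidean metric.

    Per point, s = (b - a) / max(a, b) with a the mean distance to the
    other members of its own cluster and b the smallest mean distance to
    any other cluster.  Singleton clusters score 0, as does the
    degenerate case a = b = 0 (coincident points).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    r = scores.shape[0]
    if labels.shape != (r,):
        raise ValueError("need one label per row")

    D = cdist(scores, scores)
    onehot = (labels[:, None] == uniq[None, :]).astype(float)
    counts = onehot.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("every cluster must be nonempty")
    sums = D @ onehot  # (r, k): summed distance from each point to each cluster

    own = np.searchsorted(uniq, labels)
    own_count = counts[own]
    a = np.zeros(r)
    multi = own_count > 1
    a[multi] = sums[multi, own[multi]] / (own_count[multi] - 1)

    mean_other = sums / counts[None, :]
    mean_other[np.arange(r), own] = np.inf
    b = mean_other.min(axis=1)

    denom = np.maximum(a, b)
    s = np.zeros(r)
    ok = multi & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return float(s.mean())


@dataclass
class ClusterModel:
    """k-means result with the silhouette-selected cluster count."""

    n: int
    labels: np.ndarray  # (r,) in 1..n
    centroids: np.ndarray  # (n, m) in PC-score space
    mean_silhouette: dict[int, float]  # candidate n -> mean silhouette
    seed: int
    n_candidates: tuple[int, int]
    inertia: float = field(default=float("nan"))


def select_n_and_fit(
    scores: np.ndarray,
    n_candidates: range | tuple[int, int] = (2, 8),
    seed: int = 0,
    restarts: int = 20,
) -> ClusterModel:
    """Choose the cluster count by the silhouette criterion and fit k-means.

    For each candidate n, k-means is run with greedy k-means++ seeding
    and ``restarts`` restarts, keeping the best inertia; the winning n
    maximizes the mean silhouette of the resulting partition (ties go to
    the smaller n).  Deterministic for a fixed seed.  Candidates that
    cannot produce n nonempty clusters are skipped and logged.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    r = scores.shape[0]
    if isinstance(n_candidates, range):
        cand = list(n_candidates)
    else:
        lo, hi = n_candidates
        cand = list(range(lo, hi + 1))
    if not cand or min(cand) < 2:
        raise ValueError("cluster-count candidates must start at 2 or above")
    if r <= max(cand):
        raise ValueError("need more points than the largest candidate n")

    sil: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for n in cand:
        km = KMeans(
            n_clusters=n,
            init="k-means++",
            n_init=restarts,
            max_iter=300,
            tol=1e-10,
            random_state=(seed * 1009 + n) % (2**31),
            algorithm="lloyd",
        )
        labels = km.fit_predict(scores)
        if np.unique(labels).size < n:
            logger.warning("candidate n=%d produced an empty cluster; skipped", n)
            continue
        sil[n] = mean_silhouette(scores, labels)
        fits[n] = km
    if not sil:
        raise ValueError("no cluster-count candidate produced a valid partition")

    best_n = max(sorted(sil), key=lambda n: sil[n])  # ties -> smaller n
    best = fits[best_n]
    return ClusterModel(
        n=best_n,
        labels=best.labels_ + 1,
        centroids=best.cluster_centers_,
        mean_silhouette=sil,
        seed=seed,
        n_candidates=(min(cand), max(cand)),
        inertia=float(best.inertia_),
    )


def labels_to_map(
    labels: np.ndarray,
    grid: ScanGrid,
    excluded: np.ndarray | list[int] | None = None,
) -> LabelMap:
    """Place 1-based cluster labels on the scan grid per the raster order.

    ``excluded`` lists flat curve indices (raster order) that carry no
    label; those pixels are set to 0.  The label sequence covers the
    remaining indices in order.
    """
    excluded = np.asarray(excluded if excluded is not None else [], dtype=int)
    labels = np.asarray(labels, dtype=int)
    if labels.size + excluded.size != grid.n_pixels:
        raise ValueError(
            f"{labels.size} labels + {excluded.size} excluded != "
            f"{grid.n_pixels} grid pixels"
        )
    excluded_set = set(excluded.tolist())
    out = np.zeros((grid.ny, grid.nx), dtype=int)
    it = iter(labels.tolist())
    for k in range(grid.n_pixels):
        row, col = flat_to_grid_index(k, grid)
        out[row, col] = 0 if k in excluded_set else next(it)
    return LabelMap(labels=out, grid=grid)
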