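"""Representative scattering signals per cluster.

Two extraction rules are provided.  ``centroid_nearest`` returns the
single member curve whose PC-score distance to its own centroid is
minimal -- the cluster "core".  ``furthest_mean`` averages the 10% of
members with the largest summed Euclidean distance to *all* cluster
centroids; points far from every cluster core are the least mixed, so
this rule avoids the overlapping interfaces between clusters where
signals blend.  The alternative reading (distance to the own centroid
only) is available via ``distance_rule="own"``.

Curves are reported on the normalized working grid, not rescaled to raw
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .cluster import ClusterModel
from .preprocess import CurveMatrix

__all__ = ["RepresentativeSignal", "representative_centroid", "representative_furthest"]


@dataclass
class RepresentativeSignal:
    """One curve summarizing a cluster, with extraction provenance."""

    cluster_id: int
    curve: np.ndarray
    q: np.ndarray
    method: str  # "centroid_nearest" | "furthest_mean"
    member_indices: np.ndarray  # rows (into the clustered score matrix) used

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.member_indices = np.asarray(self.member_indices, dtype=int)
        if self.curve.size != self.q.size:
            raise ValueError("curve must live on the working q grid")
        if self.member_indices.size == 0:
            raise ValueError("a representative needs at least one member")


def _cluster_members(model: ClusterModel, cluster_id: int) -> np.ndarray:
    if not 1 <= cluster_id <= model.n:
        raise ValueError(f"cluster id {cluster_id} outside 1..{model.n}")
    members = np.flatnonzero(model.labels == cluster_id)
    if members.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    return members


def representative_centroid(
    model: ClusterModel,
    scores: np.ndarray,
    curves: CurveMatrix,
    cluster_id: int,
) -> RepresentativeSignal:
    """The member curve nearest (Euclidean, PC space) to its own centroid.

    Ties are broken toward the lowest row index.
    """
    members = _cluster_members(model, cluster_id)
    d = np.linalg.norm(
        scores[members] - model.centroids[cluster_id - 1][None, :], axis=1
    )
    best = members[int(np.argmin(d))]  # argmin takes the first minimum
    return RepresentativeSignal(
        cluster_id=cluster_id,
        curve=curves.values[best].copy(),
        q=curves.q_centers,
        method="centroid_nearest",
        member_indices=np.array([best]),
    )


def representative_furthest(
    model: ClusterModel,
    scores: np.ndarray,
    curves: CurveMatrix,
    cluster_id: int,
    fraction: float = 0.10,
    distance_rule: str = "all_centroids",
) -> RepresentativeSignal:
    """Mean of the members furthest from the cluster centroids.

    Each member is scored by the sum of its Euclidean distances to all n
    centroids (``distance_rule="all_centroids"``, the default) or by the
    distance to its own centroid only (``"own"``).  The top
    ``ceil(fraction * cluster_size)`` scorers are averaged, unweighted.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if distance_rule not in ("all_centroids", "own"):
        raise ValueError(f"unknown distance rule {distance_rule!r}")
    members = _cluster_members(model, cluster_id)
    pts = scores[members]
    if distance_rule == "all_centroids":
        score = np.linalg.norm(
            pts[:, None, :] - model.centroids[None, :, :], axis=2
        ).sum(axis=1)
    else:
        score = np.linalg.norm(
            pts - model.centroids[cluster_id - 1][None, :], axis=1
        )
    k = max(1, ceil(fraction * members.size))
    # Stable selection: sort by (-score, row index) so ties keep scan order.
    order = np.lexsort((members, -score))
    chosen = np.sort(members[order[:k]])
    return RepresentativeSignal(
        cluster_id=cluster_id,
        curve=curves.values[chosen].mean(axis=0),
        q=curves.q_centers,
        method="furthest_mean",
        member_indices=chosen,
    )
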