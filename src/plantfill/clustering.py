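"""Agglomerative clustering of plant point clouds.

The merge rule follows the augmentation pipeline's recipe: clustering
starts from singletons and merges the closest pair, where the distance
between two point sets is the average pairwise distance for the very
first comparisons (which, for singletons, coincides with the distance
between their centers) and the distance *between cluster centers* after
every merge, with the new center being the size-weighted mean of the two
merged centers.  Operationally this is greedy centroid linkage; the
average-linkage variant is available behind ``method="average"`` for
cross-checking against standard libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import PointCloud

__all__ = ["Clustering", "average_linkage", "merge_centroid", "hierarchical_cluster"]


@dataclass
class Clustering:
    """Flat clustering with the merge trace that produced it.

    ``labels`` assigns every point a cluster id in ``0..k-1``; ``centroids``
    holds the per-cluster mean; ``merge_history`` records
    ``(cluster_id_a, cluster_id_b, linkage_distance)`` in merge order, with
    ids referring to the surviving representative of each cluster at the
    time of the merge.
    """

    labels: np.ndarray
    centroids: np.ndarray
    merge_history: list[tuple[int, int, float]]

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def average_linkage(ci: np.ndarray, cj: np.ndarray) -> float:
    """Mean of all pairwise Euclidean distances between two point sets."""
    ci = np.atleast_2d(np.asarray(ci, dtype=np.float64))
    cj = np.atleast_2d(np.asarray(cj, dtype=np.float64))
    if ci.size == 0 or cj.size == 0:
        raise ValueError("average_linkage requires non-empty point sets")
    diff = ci[:, None, :] - cj[None, :, :]
    return float(np.linalg.norm(diff, axis=-1).mean())


def merge_centroid(phi_i: np.ndarray, ni: int, phi_j: np.ndarray, nj: int) -> np.ndarray:
    """Size-weighted mean of two cluster centers."""
    if ni < 1 or nj < 1:
        raise ValueError("cluster sizes must be >= 1")
    phi_i = np.asarray(phi_i, dtype=np.float64)
    phi_j = np.asarray(phi_j, dtype=np.float64)
    return (phi_i * ni + phi_j * nj) / (ni + nj)


def hierarchical_cluster(cloud: PointCloud, k: int, method: str = "centroid") -> Clustering:
    """Agglomerate a cloud down to ``k`` clusters.

    ``method="centroid"`` (default) is the pipeline rule described in the
    module docstring; ``method="average"`` maintains exact average-linkage
    distances via the Lance-Williams update.  Ties are broken by the lowest
    ``(id, id)`` pair.  Runs in O(N^2) memory, O(N^2 log-ish) time; for
    large clouds, cluster a subsample and assign the rest (see
    :func:`plantfill.augment.cluster_with_assignment`).
    """
    n = len(cloud)
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= N={n}, got {k}")
    if method not in ("centroid", "average"):
        raise ValueError(f"unknown method {method!r}")

    pts = cloud.points
    centroids = pts.copy()
    sizes = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    member = np.arange(n)  # point -> current cluster representative id
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    history: list[tuple[int, int, float]] = []
    iu = np.triu_indices(n, 1)

    for _ in range(n - k):
        masked = np.where(active[:, None] & active[None, :], dist, np.inf)
        # row-major argmin over i<j == lowest (i, j) tie-break
        flat = masked[iu]
        best = int(np.argmin(flat))
        i, j = int(iu[0][best]), int(iu[1][best])
        d_ij = float(flat[best])
        history.append((i, j, d_ij))

        if method == "average":
            # Lance-Williams: d(i∪j, m) = (|i| d(i,m) + |j| d(j,m)) / (|i|+|j|)
            new_d = (sizes[i] * dist[i] + sizes[j] * dist[j]) / (sizes[i] + sizes[j])
        centroids[i] = merge_centroid(centroids[i], sizes[i], centroids[j], sizes[j])
        sizes[i] += sizes[j]
        active[j] = False
        member[member == j] = i
        if method == "centroid":
            new_d = np.linalg.norm(centroids - centroids[i], axis=1)
        new_d[i] = np.inf
        new_d[~active] = np.inf
        dist[i, :] = new_d
        dist[:, i] = new_d

    reps = np.flatnonzero(active)
    relabel = {rep: idx for idx, rep in enumerate(reps)}
    labels = np.array([relabel[r] for r in member], dtype=np.int64)
    final_centroids = np.stack([pts[labels == c].mean(axis=0) for c in range(k)])
    return Clustering(labels=labels, centroids=final_centroids, merge_history=history)
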