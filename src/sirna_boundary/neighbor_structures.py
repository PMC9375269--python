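"""Mini-group (MG) and mini-cluster (Icc) partitioning of feature matrices.

Two neighbor structures are used, each under two metrics (Euclidean distance
and Pearson-correlation distance, ``1 - r``):

* **MG mini-groups** — the minimal sets closed under the nearest-neighbor
  relation: every sample shares its group with its nearest neighbor.  These
  are exactly the weakly connected components of the directed 1-NN graph
  (edge i -> NN(i)).  MG1 uses Euclidean distance, MG2 correlation distance.
* **Icc mini-clusters** — farthest-point-seeded clustering: the first two
  centers realize the maximum pairwise distance, each further center
  maximizes its minimum distance to the chosen centers, and the remaining
  samples join their nearest center.  Icc1/Icc2 as above.  In the boundary
  method the number of clusters is set to the training-set size, so most
  clusters are singletons and only genuinely close samples share one.

All ties (nearest neighbor, nearest center, farthest pair) are broken toward
the smallest sample index, making every partition deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Partition",
    "pairwise_distances",
    "nearest_neighbor",
    "mg_partition",
    "icc_cluster",
    "mg_partition_from_distances",
    "icc_cluster_from_distances",
]

METRICS = ("euclidean", "pcc")


@dataclass(frozen=True)
class Partition:
    """Group labels (contiguous, 1-based) for a fixed sample set.

    ``centers[g-1]`` is the sample index of cluster g's center for Icc
    partitions; MG mini-groups have no centers.
    """

    labels: np.ndarray
    method: str
    n_groups: int
    centers: np.ndarray | None = None

    def members(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.labels == group)


def _pcc_distances(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    unit = centered / safe[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    D = 1.0 - corr
    if zero.any():
        # Zero-variance vectors carry no correlation signal: distance 1 to
        # everything, except 0 to an identical vector.
        D[zero, :] = 1.0
        D[:, zero] = 1.0
        for a in np.flatnonzero(zero):
            same = np.all(X == X[a], axis=1)
            D[a, same] = 0.0
            D[same, a] = 0.0
    np.fill_diagonal(D, 0.0)
    return D


def pairwise_distances(X: np.ndarray, metric: str) -> np.ndarray:
    """Symmetric n x n distance matrix under 'euclidean' or 'pcc'."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if metric == "euclidean":
        return squareform(pdist(X, metric="euclidean"))
    if metric == "pcc":
        return _pcc_distances(X)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _nn_indices(D: np.ndarray) -> np.ndarray:
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    return np.argmin(D, axis=1)  # argmin resolves ties to the smallest index


def nearest_neighbor(X: np.ndarray, metric: str, i: int) -> int:
    """Index of the nearest neighbor of sample i (self excluded)."""
    X = np.asarray(X, dtype=np.float64)
    if len(X) < 2:
        raise ValueError("nearest_neighbor needs at least 2 samples")
    return int(_nn_indices(pairwise_distances(X, metric))[i])


def mg_partition_from_distances(D: np.ndarray, method: str = "MG1") -> Partition:
    n = len(D)
    if n < 2:
        raise ValueError("MG partitioning needs at least 2 samples")
    nn = _nn_indices(D)
    graph = csr_matrix(
        (np.ones(n, dtype=np.int8), (np.arange(n), nn)), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=True, connection="weak")
    labels = np.zeros(n, dtype=np.int64)
    remap: dict[int, int] = {}
    for i in range(n):
        labels[i] = remap.setdefault(comp[i], len(remap) + 1)
    return Partition(labels, method, n_groups=len(remap))


def mg_partition(X: np.ndarray, metric: str = "euclidean") -> Partition:
    """Weakly connected components of the directed 1-NN graph."""
    method = "MG1" if metric == "euclidean" else "MG2"
    return mg_partition_from_distances(pairwise_distances(X, metric), method)


def icc_cluster_from_distances(
    D: np.ndarray, n_clusters: int, method: str = "Icc1"
) -> Partition:
    n = len(D)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in 1..{n}, got {n_clusters}")
    if n == 1:
        return Partition(
            np.array([1], dtype=np.int64), method, 1, centers=np.array([0])
        )
    # Seed with the globally farthest pair (row-major argmax ties toward the
    # smallest index pair), then farthest-first traversal.
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    centers = [int(i)] if n_clusters == 1 else [int(i), int(j)]
    min_dist = D[centers[0]].copy()
    for c in centers[1:]:
        np.minimum(min_dist, D[c], out=min_dist)
    while len(centers) < n_clusters:
        masked = min_dist.copy()
        masked[centers] = -np.inf
        nxt = int(np.argmax(masked))
        centers.append(nxt)
        np.minimum(min_dist, D[nxt], out=min_dist)
    center_arr = np.array(centers, dtype=np.int64)
    # Assign to the nearest center; ties go to the center with the smallest
    # sample index, centers always belong to their own cluster.
    order = np.argsort(center_arr, kind="stable")
    dmat = D[:, center_arr[order]]
    choice = order[np.argmin(dmat, axis=1)]
    labels = choice + 1  # cluster id = 1-based center selection order
    labels[center_arr] = np.arange(1, len(centers) + 1)
    return Partition(
        labels.astype(np.int64), method, n_groups=len(centers), centers=center_arr
    )


def icc_cluster(X: np.ndarray, n_clusters: int, metric: str = "euclidean") -> Partition:
    """Farthest-point-seeded clustering with nearest-center assignment."""
    method = "Icc1" if metric == "euclidean" else "Icc2"
    return icc_cluster_from_distances(
        pairwise_distances(X, metric), n_clusters, method
    )
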