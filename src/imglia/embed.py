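"""Sample embeddings and clustering: PCA, classical (Torgerson) MDS,
agglomerative hierarchical clustering, and cluster-recovery metrics.

These are the computations behind the identity-validation figures: MDS
of expression profiles across studies, and 2D hierarchical clustering of
the cascade-filtered signature genes.  Classical MDS follows the
cmdscale contract: double-center the squared distances, eigendecompose,
scale eigenvectors by the square roots of the non-negative eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .containers import NormalizedMatrix

__all__ = [
    "Embedding",
    "DistanceMatrix",
    "Dendrogram",
    "sample_distances",
    "pca",
    "classical_mds",
    "hierarchical_cluster",
    "cluster_purity",
    "nearest_centroid",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample×sample distances, zero diagonal."""

    d: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.d.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric (tol 1e-12)")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (arr < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.d.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.d.to_numpy(dtype=float), checks=False)


@dataclass
class Embedding:
    """Low-dimensional sample coordinates with per-axis explained shares."""

    coordinates: pd.DataFrame  # samples x k
    explained: np.ndarray
    method: Literal["pca", "cmds"]
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage encoding."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Cluster labels from cutting the tree into ``k`` clusters."""
        if k > len(self.leaf_ids):
            raise ValueError(f"cannot cut {len(self.leaf_ids)} leaves into {k} clusters")
        assignment = sch.fcluster(self.merges, t=k, criterion="maxclust")
        return pd.Series(assignment, index=self.leaf_ids, name="cluster")


def sample_distances(
    m: NormalizedMatrix, metric: Literal["euclidean", "correlation"] = "euclidean"
) -> DistanceMatrix:
    """Pairwise sample distances over the gene axis."""
    mat = m.values.to_numpy(dtype=float).T  # samples x genes
    d = squareform(pdist(mat, metric=metric))
    return DistanceMatrix(pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids))


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> None:
    """Make the largest-magnitude loading of each axis positive, in place."""
    for j in range(components.shape[1]):
        i = np.argmax(np.abs(components[:, j]))
        if components[i, j] < 0:
            components[:, j] *= -1
            scores[:, j] *= -1


def pca(m: NormalizedMatrix, k: int = 2) -> Embedding:
    """Principal-component scores of the gene-centered expression matrix."""
    X = m.values.to_numpy(dtype=float).T  # samples x genes
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if k < 1 or k > min(X.shape[1], n - 1):
        raise ValueError(f"k must be in [1, {min(X.shape[1], n - 1)}], got {k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    comps = Vt.T
    _fix_signs(comps, scores)
    total = float((S**2).sum())
    explained = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    coords = pd.DataFrame(
        scores[:, :k], index=m.sample_ids, columns=[f"axis{i+1}" for i in range(k)]
    )
    return Embedding(coords, explained, "pca")


def classical_mds(d: DistanceMatrix, k: int = 2) -> Embedding:
    """Torgerson scaling of a distance matrix (cmdscale).

    B = -1/2 · J · D² · J is double-centered; coordinates are the top-k
    eigenvectors scaled by the square roots of their (positive)
    eigenvalues.  Negative eigenvalues — non-Euclidean geometry — are
    reported on the result, never used for coordinates.
    """
    D = d.d.to_numpy(dtype=float)
    n = D.shape[0]
    if k < 1 or k > n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(abs(eigval[0]), 1.0)
    if eigval[0] <= tol:
        if np.allclose(D, 0.0):
            coords = pd.DataFrame(
                np.zeros((n, k)), index=d.sample_ids,
                columns=[f"axis{i+1}" for i in range(k)],
            )
            return Embedding(coords, np.zeros(k), "cmds")
        raise ValueError("degenerate geometry: no positive eigenvalue in the Gram matrix")
    pos = eigval > tol
    usable = min(k, int(pos.sum()))
    scores = np.zeros((n, k))
    scores[:, :usable] = eigvec[:, :usable] * np.sqrt(eigval[:usable])
    _fix_signs(eigvec[:, :usable], scores[:, :usable])
    total_pos = float(eigval[pos].sum())
    explained = np.zeros(k)
    explained[:usable] = eigval[:usable] / total_pos
    coords = pd.DataFrame(
        scores, index=d.sample_ids, columns=[f"axis{i+1}" for i in range(k)]
    )
    return Embedding(coords, explained, "cmds", negative_eigenvalues=eigval[eigval < -tol])


def hierarchical_cluster(
    d: DistanceMatrix, linkage: Literal["complete", "average", "single"] = "average"
) -> Dendrogram:
    """Agglomerative clustering of a distance matrix."""
    if len(d.sample_ids) < 2:
        raise ValueError("clustering needs at least two samples")
    if linkage not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    Z = sch.linkage(d.condensed(), method=linkage)
    return Dendrogram(Z, d.sample_ids)


def cluster_purity(
    dendro: Dendrogram, labels: Mapping[str, str] | pd.Series, k: int
) -> float:
    """Majority-class purity of the k-cluster cut, in [0, 1]."""
    labels = pd.Series(labels).loc[dendro.leaf_ids]
    assignment = dendro.cut(k)
    total = 0
    for _, members in assignment.groupby(assignment):
        total += labels.loc[members.index].value_counts().iloc[0]
    return total / len(labels)


def nearest_centroid(
    emb: Embedding,
    query_samples: Sequence[str],
    centroid_groups: Mapping[str, Sequence[str]],
) -> str:
    """Which group's centroid is closest to the mean of the query samples.

    Used as the machine-checkable form of the MDS identity question:
    are iMG cells nearer the reference-microglia centroid than the
    reference-monocyte one?
    """
    coords = emb.coordinates
    query = coords.loc[list(query_samples)].mean(axis=0).to_numpy()
    best, best_dist = None, np.inf
    for name, samples in centroid_groups.items():
        centroid = coords.loc[list(samples)].mean(axis=0).to_numpy()
        dist = float(np.linalg.norm(query - centroid))
        if dist < best_dist:
            best, best_dist = name, dist
    if best is None:
        raise ValueError("centroid_groups must be non-empty")
    return best
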