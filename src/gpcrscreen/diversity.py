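"""Diversity selection: Tanimoto-distance clustering and 2-D embedding.

Candidates are clustered on the 1 - Tanimoto distance matrix of their
circular fingerprints with average-linkage agglomerative clustering; the
number of clusters can be chosen automatically by silhouette score, and
each cluster is represented by its medoid (the member with minimal
summed intra-cluster distance).  PCA to 50 components followed by t-SNE
(perplexity 30, learning rate 200, 5000 iterations) provides the 2-D map
used for visual inspection only — never for clustering decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .chemfp import BitFingerprint, bulk_tanimoto


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match id count")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray           # cluster index per molecule, 0..k-1
    silhouette: float
    representatives: list[str]   # one medoid id per cluster

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]


def tanimoto_distance_matrix(fps: Sequence[BitFingerprint]) -> DistanceMatrix:
    """1 - Tanimoto over all fingerprint pairs."""
    if len(fps) < 2:
        raise ValueError("need at least 2 fingerprints")
    lengths = {len(f) for f in fps}
    if len(lengths) != 1:
        raise ValueError(f"fingerprint length mismatch {sorted(lengths)}")
    sim = bulk_tanimoto(fps)
    return DistanceMatrix(ids=[f.molecule_id for f in fps], values=1.0 - sim)


def pca_embed(matrix: DistanceMatrix | np.ndarray,
              components: int = 50) -> np.ndarray:
    """PCA of the distance-matrix rows (or any sample matrix), clamped to
    min(components, n).

    Columns are ordered by decreasing explained variance.  Component
    signs are fixed by forcing the largest-magnitude loading of each
    component positive, making the embedding deterministic.
    """
    data = matrix.values if isinstance(matrix, DistanceMatrix) else np.asarray(
        matrix, dtype=float)
    n = data.shape[0]
    if n < 2:
        raise ValueError("need n >= 2")
    k = min(components, n, data.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    emb = pca.fit_transform(data)
    for j in range(emb.shape[1]):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            emb[:, j] *= -1
    return emb


def _medoid(indices: np.ndarray, dist: np.ndarray, ids: list[str]) -> str:
    sums = dist[np.ix_(indices, indices)].sum(axis=1)
    best = sums.min()
    # ties break by id order
    tied = sorted(ids[i] for i in indices[np.isclose(sums, best)])
    return tied[0]


def cluster_hierarchical(matrix: DistanceMatrix, k: int,
                         method: str = "average") -> ClusterAssignment:
    """Average-linkage agglomerative clustering cut at ``k`` clusters,
    with silhouette computed on the precomputed distance matrix."""
    n = len(matrix)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} outside valid range [2, {n - 1}]")
    Z = linkage(squareform(matrix.values, checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel to 0..k-1 in order of first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.array([remap.setdefault(c, len(remap)) for c in raw])
    k_actual = len(remap)
    sil = float(silhouette_score(matrix.values, labels, metric="precomputed")
                ) if k_actual > 1 else -1.0
    reps = [_medoid(np.nonzero(labels == c)[0], matrix.values, matrix.ids)
            for c in range(k_actual)]
    return ClusterAssignment(k=k_actual, labels=labels, silhouette=sil,
                             representatives=reps)


def select_k_by_silhouette(matrix: DistanceMatrix,
                           k_range: Sequence[int],
                           method: str = "average") -> ClusterAssignment:
    """Pick the cluster count maximizing silhouette; ties go to smaller k."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    best: ClusterAssignment | None = None
    for k in ks:
        cand = cluster_hierarchical(matrix, k, method=method)
        if best is None or cand.silhouette > best.silhouette + 1e-12:
            best = cand
    assert best is not None
    return best


def tsne_embed(matrix: DistanceMatrix, perplexity: float = 30.0,
               learning_rate: float = 200.0, iterations: int = 5000,
               seed: int = 0, pca_components: int = 50) -> np.ndarray:
    """2-D t-SNE of the PCA-reduced distance matrix, for inspection only.

    If n is too small for the requested perplexity it is reduced with a
    warning (t-SNE requires perplexity < n).
    """
    n = len(matrix)
    if n < 5:
        raise ValueError("t-SNE embedding needs n >= 5")
    if n <= 3 * perplexity:
        new_p = max(2.0, (n - 1) / 3.0)
        warnings.warn(f"perplexity {perplexity} too large for n={n}; "
                      f"reduced to {new_p}", RuntimeWarning, stacklevel=2)
        perplexity = new_p
    emb = pca_embed(matrix, components=pca_components)
    tsne = TSNE(n_components=2, perplexity=perplexity,
                learning_rate=learning_rate, max_iter=iterations,
                random_state=seed, init="pca")
    return tsne.fit_transform(emb)


def pick_representatives(assignment: ClusterAssignment,
                         matrix: DistanceMatrix) -> list[str]:
    """Cluster medoids: member minimizing summed intra-cluster distance.

    A stand-in for manual visual inspection of clusters; ties break by
    molecule id so the selection is reproducible.
    """
    return [_medoid(assignment.members(c), matrix.values, matrix.ids)
            for c in range(assignment.k)]
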