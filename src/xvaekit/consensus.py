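"""Consensus clustering over repeatedly sampled latent embeddings.

Each sampled embedding is clustered with KMeans; the binary co-assignment
matrices are averaged into a consensus matrix, which is then partitioned
with spectral clustering (the consensus matrix acts as the graph affinity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans, SpectralClustering

__all__ = [
    "ConsensusMatrix",
    "coassignment_matrix",
    "build_consensus",
    "spectral_cluster",
    "consensus_cluster_pipeline",
]


@dataclass
class ConsensusMatrix:
    """n x n co-clustering frequency matrix aggregated over draws."""

    matrix: np.ndarray
    n_draws: int
    k: int

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("consensus matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("consensus matrix must be symmetric")
        if m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0,1]")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("consensus diagonal must be all 1")
        self.matrix = m

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def coassignment_matrix(labels) -> np.ndarray:
    """Binary matrix with entry (i,j) = 1 iff labels[i] == labels[j]."""
    lab = np.asarray(labels).ravel()
    return (lab[:, None] == lab[None, :]).astype(np.float64)


def build_consensus(embeddings, k: int, kmeans_inits: int = 10,
                    seed: int = 0) -> ConsensusMatrix:
    """KMeans each embedding and average the co-assignment matrices."""
    embeddings = list(embeddings)
    if not embeddings:
        raise ValueError("need at least one embedding")
    n = embeddings[0].shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    acc = np.zeros((n, n))
    # one shared random_state: identical embeddings yield identical
    # clusterings, so consensus variation reflects embedding variation only
    for emb in embeddings:
        if emb.shape[0] != n:
            raise ValueError("embeddings must share the sample count")
        km = KMeans(n_clusters=k, n_init=kmeans_inits, random_state=seed)
        acc += coassignment_matrix(km.fit_predict(emb))
    return ConsensusMatrix(acc / len(embeddings), n_draws=len(embeddings), k=k)


def spectral_cluster(cm: ConsensusMatrix, k: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering with cm.matrix as the affinity."""
    if k == 1:
        return np.zeros(cm.n, dtype=np.int64)
    n_comp, _ = connected_components((cm.matrix > 0).astype(np.int8), directed=False)
    if n_comp > k:
        warnings.warn(
            f"consensus graph has {n_comp} components but k={k}; "
            "components will be merged by spectral-embedding distance",
            stacklevel=2,
        )
    sc = SpectralClustering(n_clusters=k, affinity="precomputed",
                            random_state=seed, assign_labels="kmeans", n_init=10)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Graph is not fully connected")
        labels = sc.fit_predict(cm.matrix)
    return labels.astype(np.int64)


def consensus_cluster_pipeline(model, x1: np.ndarray, x2: np.ndarray, k: int,
                               n_draws: int = 50, seed: int = 0,
                               conditioning: np.ndarray | None = None,
                               keep_dims=None):
    """Sample latent embeddings, build the consensus matrix and partition it.

    Parameters
    ----------
    model : trained XvaeModel (or conditional variant)
    conditioning : conditioning covariates, required by conditional models
    keep_dims : optional indices of latent dims retained before clustering
        (feature-selection variant); applied to every sampled embedding

    Returns
    -------
    (labels, ConsensusMatrix)
    """
    from .xvae import encode, sample_latent

    post = encode(model, x1, x2, conditioning=conditioning)
    draws = sample_latent(post, n_draws, seed=seed)
    if keep_dims is not None:
        keep = np.asarray(keep_dims, dtype=np.int64)
        draws = [d[:, keep] for d in draws]
    cm = build_consensus(draws, k=k, seed=seed)
    labels = spectral_cluster(cm, k=k, seed=seed)
    return labels, cm
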