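"""Encoder contract and built-in encoders.

The instance regressor is encoder-agnostic: any N x d real matrix aligned to
the cell table works.  Self-supervised encoders trained on cell image crops
are consumed as external files; built-in encoders cover the one-hot label
encoding used in idealised experiments and a synthetic cluster encoder that
emulates cluster-informative embeddings with isotropic noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .core_io import EmbeddingMatrix


@dataclass
class EncoderSpec:
    """What produced (or will produce) an embedding matrix."""

    kind: str  # "external_file" | "one_hot" | "synthetic_cluster"
    dim: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("external_file", "one_hot", "synthetic_cluster"):
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if self.dim <= 0:
            raise ValueError("encoder dim must be positive")


def _default_ids(n: int) -> np.ndarray:
    return np.array([f"cell{i}" for i in range(n)], dtype=object)


def one_hot_encode(
    labels: np.ndarray, K: int, cell_ids: np.ndarray | None = None
) -> EmbeddingMatrix:
    """One-hot encode integer labels in {0..K-1}: row i is the basis vector e_{labels[i]}."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError(f"label outside [0, {K}): {labels.max()}")
    values = np.zeros((len(labels), K))
    values[np.arange(len(labels)), labels] = 1.0
    ids = _default_ids(len(labels)) if cell_ids is None else np.asarray(cell_ids, object)
    return EmbeddingMatrix(values=values, cell_ids=ids, encoder_tag="one_hot")


def synthetic_cluster_encode(
    labels: np.ndarray,
    d: int,
    noise_sd: float,
    seed: int,
    cell_ids: np.ndarray | None = None,
) -> EmbeddingMatrix:
    """Cluster-informative synthetic embeddings.

    Each cluster receives a fixed random unit-norm anchor in R^d (seeded);
    a cell's embedding is its cluster anchor plus isotropic Gaussian noise of
    scale ``noise_sd``.  With ``noise_sd=0`` same-cluster rows are identical.
    """
    labels = np.asarray(labels, dtype=np.int64)
    K = int(labels.max()) + 1 if labels.size else 0
    if d < K:
        raise ValueError(f"embedding dim {d} < number of clusters {K}")
    rng = np.random.default_rng(seed)
    anchors = rng.normal(size=(max(K, 1), d))
    anchors /= np.linalg.norm(anchors, axis=1, keepdims=True)
    values = anchors[labels] + rng.normal(scale=noise_sd, size=(len(labels), d))
    ids = _default_ids(len(labels)) if cell_ids is None else np.asarray(cell_ids, object)
    return EmbeddingMatrix(values=values, cell_ids=ids, encoder_tag="synthetic_cluster")


def kmeans_cluster(
    E: EmbeddingMatrix, k: int, seed: int, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means with k-means++ initialisation, best of ``n_init`` restarts.

    Deterministic given ``seed``.  Returns (labels, centroids).
    """
    if E.n_cells < k:
        raise ValueError(f"cannot form {k} clusters from {E.n_cells} cells")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-4,
        random_state=seed,
    ).fit(E.values)
    return km.labels_.astype(np.int64), km.cluster_centers_


def nearest_to_centroid(
    E: EmbeddingMatrix,
    labels: np.ndarray,
    centroids: np.ndarray,
    keep: int = 2000,
) -> np.ndarray:
    """Per cluster, the ``keep`` cells closest to their centroid (indices, ascending).

    Retaining only cells near the centroids sharpens the morphological
    separation between clusters.  Clusters smaller than ``keep`` are kept
    whole with a warning; ties at the cutoff resolve to the lower cell index.
    """
    labels = np.asarray(labels, dtype=np.int64)
    selected: list[np.ndarray] = []
    for c in range(centroids.shape[0]):
        idx = np.where(labels == c)[0]
        if len(idx) == 0:
            continue
        if len(idx) < keep:
            warnings.warn(
                f"cluster {c} has {len(idx)} cells < keep={keep}; keeping all",
                stacklevel=2,
            )
            selected.append(idx)
            continue
        d = np.linalg.norm(E.values[idx] - centroids[c], axis=1)
        order = np.lexsort((idx, d))[:keep]  # distance, then lower index
        selected.append(idx[order])
    return np.sort(np.concatenate(selected)) if selected else np.array([], dtype=np.int64)
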