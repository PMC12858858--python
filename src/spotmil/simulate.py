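"""Simulation framework: controlled coupling between morphology and expression.

The framework builds fully synthetic datasets in which the strength of the
association between a cell's image-derived embedding and its expression
profile is known by construction:

* ``random`` — expression vectors are drawn from the whole reference
  independently of the morphology cluster (no association; a trained model
  should score a mean correlation of about zero);
* ``centroid`` — every cell of a morphology cluster receives the mean
  profile of its matched reference cluster (perfect association, no
  intra-cluster variability);
* ``cell`` — each cell receives the profile of a random cell from the
  matched reference cluster (inter-cluster association only; intra-cluster
  expression variability is independent of morphology).

Morphology clusters come from k-means (k = 6) on the embeddings; only the
cells closest to each centroid are retained to sharpen the clusters, and the
morphology-to-reference cluster matching is an arbitrary (seeded) bijection.
Spots are formed by sampling member cells and summing their expression
exactly, so spot counts conserve the member-cell counts by construction.

A synthetic clustered single-cell reference generator is included so the
whole pipeline runs without any external download: cluster-specific
negative-binomial expression with designated marker genes whose mean is
multiplied by a fold change in their own cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import (
    BagAssignment,
    CellTable,
    EmbeddingMatrix,
    SpotCounts,
    derive_seed,
)
from .embed import kmeans_cluster, nearest_to_centroid, one_hot_encode, synthetic_cluster_encode
from .preprocess import select_hvg


@dataclass
class Reference:
    """Annotated single-cell reference: counts, cluster labels, markers, HVGs."""

    counts: np.ndarray
    cluster: np.ndarray
    gene_ids: list
    marker_sets: dict[int, list]
    hvg_ids: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cluster = np.asarray(self.cluster, dtype=np.int64)
        if self.counts.shape[0] != len(self.cluster):
            raise ValueError("counts rows must match cluster labels")
        gene_set = set(self.gene_ids)
        for c, genes in self.marker_sets.items():
            missing = [g for g in genes if g not in gene_set]
            if missing:
                raise ValueError(f"marker genes absent from reference: {missing}")
        for c in range(self.n_clusters):
            if (self.cluster == c).sum() == 0:
                raise ValueError(f"cluster {c} is empty")

    @property
    def n_clusters(self) -> int:
        return int(self.cluster.max()) + 1

    def cluster_mean(self, c: int) -> np.ndarray:
        return self.counts[self.cluster == c].mean(axis=0)


@dataclass
class ScenarioConfig:
    scenario: str = "cell"  # "random" | "centroid" | "cell"
    k_image_clusters: int = 6
    keep_per_cluster: int = 2000
    n_spots: int = 5000
    cells_per_spot: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("random", "centroid", "cell"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("k_image_clusters", "keep_per_cluster", "n_spots", "cells_per_spot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulatedDataset:
    """One simulated slide: per-cell truth, embeddings, bags and spot counts."""

    cell_expression: np.ndarray
    embeddings: EmbeddingMatrix
    bags: BagAssignment
    spot_counts: SpotCounts
    truth_labels: np.ndarray
    cells: CellTable | None = None

    def __post_init__(self) -> None:
        # conservation: every spot's counts are the exact sum of its members
        for s, members in self.bags.spot_to_cells.items():
            row = np.asarray(self.cell_expression)[members].sum(axis=0)
            if not np.array_equal(
                np.asarray(row, dtype=np.int64), self.spot_counts.counts[s]
            ):
                raise ValueError(f"spot {s} counts are not the sum of member cells")


# ---------------------------------------------------------------------------
# Synthetic reference
# ---------------------------------------------------------------------------

def generate_reference(
    K: int = 6,
    G: int = 300,
    cells_per_cluster: int = 500,
    markers_per_cluster: int = 5,
    base_mean: float = 0.5,
    fold_change: float = 5.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> Reference:
    """Draw a clustered negative-binomial single-cell reference.

    Per-gene base means are log-normal around ``base_mean`` (a realistic
    skewed mean distribution); the first ``markers_per_cluster`` genes of
    each cluster's marker block have their mean multiplied by
    ``fold_change`` in that cluster only.  ``dispersion`` is the NB inverse
    overdispersion (variance ``mu + mu^2/dispersion``).  HVGs are ranked on
    the reference itself so downstream gene lists never depend on simulated
    spots.
    """
    if markers_per_cluster * K > G:
        raise ValueError("markers_per_cluster * K exceeds G")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{j}" for j in range(G)]
    base = base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=G)
    means = np.tile(base, (K, 1))
    marker_sets: dict[int, list] = {}
    for c in range(K):
        block = slice(c * markers_per_cluster, (c + 1) * markers_per_cluster)
        means[c, block] *= fold_change
        marker_sets[c] = [gene_ids[j] for j in range(block.start, block.stop)]
    cluster = np.repeat(np.arange(K), cells_per_cluster)
    mu = means[cluster]
    p = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p)
    ref = Reference(
        counts=counts.astype(np.int64),
        cluster=cluster,
        gene_ids=gene_ids,
        marker_sets=marker_sets,
        hvg_ids=[],
    )
    ref.hvg_ids = select_hvg([ref.counts], gene_ids, n=G).gene_ids
    return ref


# ---------------------------------------------------------------------------
# Scenario machinery
# ---------------------------------------------------------------------------

def match_clusters(
    image_labels: np.ndarray, reference: Reference, seed: int
) -> dict[int, int]:
    """Arbitrary (seeded) bijection image cluster -> reference cluster."""
    k_img = int(np.asarray(image_labels).max()) + 1
    if k_img != reference.n_clusters:
        raise ValueError(
            f"{k_img} image clusters vs {reference.n_clusters} reference clusters"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(k_img)
    return {int(i): int(perm[i]) for i in range(k_img)}


def assign_expression(
    scenario: str,
    image_labels: np.ndarray,
    cluster_map: dict[int, int],
    reference: Reference,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign a ground-truth expression vector to every cell.

    Returns (N x G expression, source reference-cluster per cell).  In the
    centroid scenario the cluster mean profile is rounded to the nearest
    integer so counts stay integral end to end.
    """
    labels = np.asarray(image_labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    M = reference.counts.shape[0]
    if scenario == "random":
        rows = rng.integers(0, M, size=len(labels))
        return reference.counts[rows].copy(), reference.cluster[rows].copy()
    if scenario == "centroid":
        profiles = np.vstack(
            [
                np.round(reference.cluster_mean(cluster_map[c])).astype(np.int64)
                for c in range(reference.n_clusters)
            ]
        )
        src = np.array([cluster_map[int(c)] for c in labels])
        return profiles[labels].copy(), src
    if scenario == "cell":
        expr = np.empty((len(labels), reference.counts.shape[1]), dtype=np.int64)
        src = np.empty(len(labels), dtype=np.int64)
        for c in np.unique(labels):
            ref_c = cluster_map[int(c)]
            pool = np.where(reference.cluster == ref_c)[0]
            sel = labels == c
            rows = rng.choice(pool, size=int(sel.sum()), replace=True)
            expr[sel] = reference.counts[rows]
            src[sel] = ref_c
        return expr, src
    raise ValueError(f"unknown scenario {scenario!r}")


def simulate_spots(
    cell_expression: np.ndarray,
    n_spots: int,
    cells_per_spot: int,
    seed: int,
    *,
    embeddings: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    encoder_tag: str = "synthetic_cluster",
    slide_id: str = "sim",
    spot_radius: float = 50.0,
    spot_spacing: float = 150.0,
) -> SimulatedDataset:
    """Form spots by sampling member cells and summing their expression.

    Pool cells are sampled with replacement across spots but without
    replacement within a spot; every draw is materialised as a distinct
    cell instance so each instance belongs to exactly one bag.  Spot centres
    sit on a square grid; each instance receives a position inside its spot.
    """
    expr_pool = np.asarray(cell_expression)
    n_pool = expr_pool.shape[0]
    if cells_per_spot > n_pool:
        raise ValueError("cells_per_spot exceeds the cell pool")
    rng = np.random.default_rng(seed)
    draws = np.vstack(
        [rng.choice(n_pool, size=cells_per_spot, replace=False) for _ in range(n_spots)]
    )
    flat = draws.ravel()
    inst_expr = expr_pool[flat]
    n_inst = len(flat)

    side = int(np.ceil(np.sqrt(n_spots)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    spot_xy = (
        np.column_stack([gx.ravel(), gy.ravel()])[:n_spots] * spot_spacing
        + spot_spacing
    ).astype(float)

    # instances scattered uniformly inside their spot's capture disc
    theta = rng.uniform(0, 2 * np.pi, n_inst)
    r = spot_radius * np.sqrt(rng.uniform(0, 1, n_inst))
    inst_xy = np.repeat(spot_xy, cells_per_spot, axis=0) + np.column_stack(
        [r * np.cos(theta), r * np.sin(theta)]
    )

    spot_mat = inst_expr.reshape(n_spots, cells_per_spot, -1).sum(axis=1)
    bags = BagAssignment(
        {
            s: np.arange(s * cells_per_spot, (s + 1) * cells_per_spot)
            for s in range(n_spots)
        }
    )
    gene_ids = [f"g{j}" for j in range(expr_pool.shape[1])]
    cell_ids = np.array([f"{slide_id}_c{i}" for i in range(n_inst)], dtype=object)
    sc = SpotCounts(
        counts=spot_mat.astype(np.int64),
        spot_ids=np.array([f"{slide_id}_s{i}" for i in range(n_spots)], dtype=object),
        gene_ids=np.array(gene_ids, dtype=object),
        slide_id=slide_id,
        spot_xy=spot_xy,
        spot_radius=spot_radius,
    )
    emb = None
    if embeddings is not None:
        emb = EmbeddingMatrix(
            values=np.asarray(embeddings)[flat],
            cell_ids=cell_ids,
            encoder_tag=encoder_tag,
        )
    truth = np.asarray(labels)[flat] if labels is not None else np.full(n_inst, -1)
    cells = CellTable(cell_ids=cell_ids, slide_id=slide_id, cell_xy=inst_xy)
    return SimulatedDataset(
        cell_expression=inst_expr,
        embeddings=emb
        if emb is not None
        else EmbeddingMatrix(np.zeros((n_inst, 1)), cell_ids, "none"),
        bags=bags,
        spot_counts=sc,
        truth_labels=truth,
        cells=cells,
    )


def run_scenario(
    cfg: ScenarioConfig,
    reference: Reference,
    embeddings: EmbeddingMatrix | None = None,
    pool_labels: np.ndarray | None = None,
    *,
    pool_size: int = 15_000,
    embed_dim: int = 16,
    embed_noise_sd: float = 0.10,
    one_hot: bool = False,
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Full pipeline: cluster embeddings, match, assign expression, form spots.

    When no embeddings are supplied a synthetic pool of ``pool_size`` cells
    with uniform cluster labels is encoded by the synthetic cluster encoder
    (or one-hot on the labels with ``one_hot=True``).  k-means (k =
    ``k_image_clusters``) recovers morphology clusters, the
    ``keep_per_cluster`` cells nearest each centroid are retained, a seeded
    bijection matches image to reference clusters, and train/test datasets
    are sampled independently with derived seeds (the cluster matching is
    shared, expression assignment and spot membership are fresh).
    """
    K = cfg.k_image_clusters
    if embeddings is None:
        rng_pool = np.random.default_rng(derive_seed(cfg.seed, "pool"))
        pool_labels = rng_pool.integers(0, K, size=pool_size)
        if one_hot:
            embeddings = one_hot_encode(pool_labels, K)
        else:
            embeddings = synthetic_cluster_encode(
                pool_labels, embed_dim, embed_noise_sd, derive_seed(cfg.seed, "encode")
            )
    img_labels, centroids = kmeans_cluster(
        embeddings, K, seed=derive_seed(cfg.seed, "kmeans")
    )
    keep = nearest_to_centroid(embeddings, img_labels, centroids, cfg.keep_per_cluster)
    E_keep = embeddings.values[keep]
    labels_keep = img_labels[keep]
    cmap = match_clusters(labels_keep, reference, derive_seed(cfg.seed, "match"))

    out = []
    for split in ("train", "test"):
        expr, src = assign_expression(
            cfg.scenario,
            labels_keep,
            cmap,
            reference,
            derive_seed(cfg.seed, f"assign-{split}"),
        )
        ds = simulate_spots(
            expr,
            cfg.n_spots,
            cfg.cells_per_spot,
            derive_seed(cfg.seed, f"spots-{split}"),
            embeddings=E_keep,
            labels=src,
            encoder_tag=embeddings.encoder_tag,
            slide_id=f"sim_{split}",
        )
        out.append(ds)
    return out[0], out[1]
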