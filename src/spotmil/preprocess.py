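"""Quality filters, normalisation, gene selection and bag construction.

Conventions fixed here for reproducibility:

* quantiles use linear interpolation;
* genes with zero interquartile range are centred only (spread treated as 1);
* the spatial weight matrix for Moran's I is a symmetrised binary k-nearest
  neighbour graph (k defaults to 6, the hexagonal neighbourhood of a Visium
  spot), not row-normalised;
* Moran's I scores are shifted by +1 (from [-1, 1] into [0, 2]) before the
  across-slide geometric mean, which keeps the mean defined and preserves
  single-slide ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core_io import BagAssignment, CellTable, SpotCounts


@dataclass
class NormalizedMatrix:
    """Library-size log-normalised (and optionally gene-scaled) expression."""

    values: np.ndarray
    scale_constant: float = 10_000.0
    #: per-slide {slide: (center G-vector, spread G-vector)}; empty if unscaled
    scaler_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalised values must be finite")


@dataclass
class GeneSelection:
    """An ordered gene list with the per-gene statistic that ranked it."""

    gene_ids: list
    method: str  # "HVG" | "SVG" | "custom"
    statistic: np.ndarray

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        if len(self.gene_ids) != len(self.statistic):
            raise ValueError("gene_ids and statistic lengths differ")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    sc: SpotCounts,
    bags: BagAssignment,
    *,
    min_gene_counts: int = 200,
    min_detect_frac: float = 0.10,
    min_spot_counts: int = 20,
    train_spots: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean keep-masks for genes and spots; the matrix is not mutated.

    A gene is kept iff its slide-wide total is >= ``min_gene_counts`` and it
    is detected (count > 0) in at least ``min_detect_frac`` of the spots
    (training spots only when ``train_spots`` indices are given).  A spot is
    kept iff it has at least one assigned cell and a total of at least
    ``min_spot_counts``.
    """
    counts = sc.counts
    spot_totals = counts.sum(axis=1)
    has_cells = np.zeros(sc.n_spots, dtype=bool)
    for s, cells in bags.spot_to_cells.items():
        if len(cells):
            has_cells[s] = True
    spot_mask = has_cells & (spot_totals >= min_spot_counts)

    gene_totals = counts.sum(axis=0)
    det_mask = spot_mask.copy()
    if train_spots is not None:
        in_train = np.zeros(sc.n_spots, dtype=bool)
        in_train[np.asarray(train_spots)] = True
        det_mask &= in_train
    det_rows = counts[det_mask]
    detect_frac = (det_rows > 0).mean(axis=0) if det_rows.shape[0] else np.zeros(sc.n_genes)
    gene_mask = (gene_totals >= min_gene_counts) & (detect_frac >= min_detect_frac)

    if not gene_mask.any():
        raise ValueError(
            "qc_filter removed every gene; review the min_gene_counts/"
            "min_detect_frac thresholds"
        )
    return gene_mask, spot_mask


# ---------------------------------------------------------------------------
# Normalisation and scaling
# ---------------------------------------------------------------------------

def lognormalize(y: np.ndarray, s: float = 10_000.0) -> np.ndarray:
    """``ln(1 + s * y_j / sum_j y_j)`` per vector (rows of a matrix).

    Scale-invariant in the counts: doubling every entry leaves the result
    unchanged.  All-zero vectors are rejected (such spots fail QC upstream).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        tot = y.sum()
        if tot <= 0:
            raise ValueError("cannot log-normalise an all-zero vector")
        return np.log1p(s * y / tot)
    tot = y.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        bad = int(np.where(tot.ravel() <= 0)[0][0])
        raise ValueError(f"cannot log-normalise all-zero row {bad}")
    return np.log1p(s * y / tot)


def robust_scale(
    values: np.ndarray,
    slide_per_spot: np.ndarray | None = None,
    *,
    with_centering: bool = True,
) -> tuple[np.ndarray, dict]:
    """Per-gene robust scaling, applied slide by slide.

    Each gene is divided by its interquartile range (q75 - q25, linear
    interpolation quantiles); with ``with_centering`` the median is
    subtracted first.  Genes with zero IQR are divided by 1.  Returns the
    scaled matrix and ``{slide: (center, spread)}`` parameters for
    :func:`inverse_robust_scale`.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    slides = (
        np.zeros(n, dtype=object)
        if slide_per_spot is None
        else np.asarray(slide_per_spot, dtype=object)
    )
    out = np.empty_like(values)
    params: dict = {}
    for slide in _unique_keep_order(slides):
        rows = np.where(slides == slide)[0]
        block = values[rows]
        q25, med, q75 = np.percentile(block, [25, 50, 75], axis=0)
        spread = q75 - q25
        spread = np.where(spread == 0, 1.0, spread)
        center = med if with_centering else np.zeros_like(med)
        out[rows] = (block - center) / spread
        params[slide] = (center, spread)
    return out, params


def _unique_keep_order(arr: np.ndarray) -> list:
    seen: set = set()
    out = []
    for a in arr:
        if a not in seen:
            seen.add(a)
            out.append(a)
    return out


def inverse_robust_scale(
    scaled: np.ndarray, params: dict, slide_per_spot: np.ndarray | None = None
) -> np.ndarray:
    """Invert :func:`robust_scale` (identity on non-degenerate genes)."""
    scaled = np.asarray(scaled, dtype=float)
    n = scaled.shape[0]
    slides = (
        np.zeros(n, dtype=object)
        if slide_per_spot is None
        else np.asarray(slide_per_spot, dtype=object)
    )
    out = np.empty_like(scaled)
    for slide, (center, spread) in params.items():
        rows = np.where(slides == slide)[0]
        out[rows] = scaled[rows] * spread + center
    return out


# ---------------------------------------------------------------------------
# Highly variable genes (variance-stabilised, batch-aware)
# ---------------------------------------------------------------------------

def _standardized_variance(counts: np.ndarray) -> np.ndarray:
    """Per-gene standardised variance after a mean-variance trend correction.

    A lowess curve of log10(variance) on log10(mean) estimates the expected
    variance at each gene's mean; counts are standardised by the expected
    standard deviation, clipped at sqrt(N), and the variance of the clipped
    values is the gene's statistic.  Genes never detected score 0.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    stat = np.zeros(counts.shape[1])
    ok = (mean > 0) & (var > 0)
    if not ok.any():
        return stat
    x = np.log10(mean[ok])
    y = np.log10(var[ok])
    if len(np.unique(x)) < 5:
        # too few distinct means to fit a trend: treat it as flat
        exp_var = np.full(ok.sum(), 10 ** y.mean())
    else:
        fit = lowess(y, x, frac=0.3, return_sorted=True)
        exp_var = 10 ** np.interp(x, fit[:, 0], fit[:, 1])
    exp_sd = np.sqrt(exp_var)
    clip = np.sqrt(n)
    z = (counts[:, ok] - mean[ok]) / exp_sd
    z = np.clip(z, -clip, clip)
    stat[ok] = np.square(z - z.mean(axis=0)).sum(axis=0) / (n - 1)
    return stat


def select_hvg(
    counts_per_batch: list[np.ndarray],
    gene_ids: list,
    n: int,
) -> GeneSelection:
    """Top-``n`` highly variable genes, aggregated across batches.

    Within each batch genes are ranked by standardised variance; across
    batches genes are ordered by (number of batches in which the gene is in
    the per-batch top ``n``, descending) then by median within-batch rank
    (ascending).  Batch-aware selection avoids picking genes that are
    variable on a single slide only.
    """
    G = len(gene_ids)
    if n > G:
        raise ValueError(f"requested {n} HVGs from only {G} genes")
    stats = np.vstack([_standardized_variance(np.asarray(c)) for c in counts_per_batch])
    # rank 1 = most variable; stable ties by gene index
    ranks = np.empty_like(stats)
    for b in range(stats.shape[0]):
        order = np.lexsort((np.arange(G), -stats[b]))
        ranks[b, order] = np.arange(1, G + 1)
    in_top = (ranks <= n).sum(axis=0)
    med_rank = np.median(ranks, axis=0)
    order = np.lexsort((np.arange(G), med_rank, -in_top))
    chosen = order[:n]
    return GeneSelection(
        gene_ids=[gene_ids[i] for i in chosen],
        method="HVG",
        statistic=np.median(stats, axis=0)[chosen],
    )


# ---------------------------------------------------------------------------
# Spatially variable genes (Moran's I)
# ---------------------------------------------------------------------------

def _knn_weights(spot_xy: np.ndarray, n_neighbors: int) -> sparse.csr_matrix:
    """Symmetrised binary k-NN adjacency (w_ij = 1 if i in kNN(j) or vice versa)."""
    n = spot_xy.shape[0]
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(spot_xy)
    graph = nn.kneighbors_graph(spot_xy, mode="connectivity")
    graph = graph.tolil()
    graph.setdiag(0)
    graph = graph.tocsr()
    w = graph.maximum(graph.T)
    w.eliminate_zeros()
    return w


def morans_i(
    values: np.ndarray,
    spot_xy: np.ndarray,
    n_neighbors: int = 6,
    *,
    weights: sparse.spmatrix | None = None,
) -> float:
    """Moran's spatial autocorrelation index with binary symmetric k-NN weights.

    ``I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2``.
    Positive for spatially smooth fields, negative for alternating ones.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I requires at least 3 spots")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant field: Moran's I undefined")
    w = _knn_weights(np.asarray(spot_xy, float), n_neighbors) if weights is None else sparse.csr_matrix(weights)
    W = w.sum()
    num = float(z @ (w @ z))
    return (n / W) * num / denom


def select_svg(
    slides: list[tuple[np.ndarray, np.ndarray]],
    gene_ids: list,
    n: int,
    n_neighbors: int = 6,
) -> GeneSelection:
    """Top-``n`` spatially variable genes by across-slide geometric mean Moran's I.

    ``slides`` is a list of ``(counts S x G, spot_xy S x 2)`` pairs sharing the
    gene axis.  Per slide, Moran's I is computed on log-normalised values;
    scores are shifted by +1 before the geometric mean so that negative
    autocorrelation does not make the mean undefined.  Genes constant on a
    slide receive I = 0 (no spatial signal) on that slide.
    """
    G = len(gene_ids)
    if n > G:
        raise ValueError(f"requested {n} SVGs from only {G} genes")
    scores = np.zeros((len(slides), G))
    for si, (counts, xy) in enumerate(slides):
        vals = lognormalize(np.asarray(counts, dtype=float))
        w = _knn_weights(np.asarray(xy, float), n_neighbors)
        for g in range(G):
            col = vals[:, g]
            if np.ptp(col) == 0:
                scores[si, g] = 0.0
            else:
                scores[si, g] = morans_i(col, xy, n_neighbors, weights=w)
    shifted = scores + 1.0  # I in [-1, 1] -> [0, 2]
    gmean = np.exp(np.log(np.maximum(shifted, 1e-300)).mean(axis=0))
    order = np.lexsort((np.arange(G), -gmean))[:n]
    return GeneSelection(
        gene_ids=[gene_ids[i] for i in order],
        method="SVG",
        statistic=gmean[order],
    )


# ---------------------------------------------------------------------------
# Cell-to-spot linkage
# ---------------------------------------------------------------------------

def assign_cells_to_spots(cells: CellTable, sc: SpotCounts) -> tuple[BagAssignment, np.ndarray]:
    """Link each cell to its spot: nearest centre within the spot radius.

    The boundary is inclusive (distance exactly equal to the radius counts as
    inside); equidistant ties resolve to the lower spot index.  Returns the
    bag assignment and the indices of unassigned cells.
    """
    tree = cKDTree(sc.spot_xy)
    members: dict[int, list[int]] = {}
    unassigned: list[int] = []
    r = sc.spot_radius * (1 + 1e-12)  # tolerate fp rounding on the boundary
    hits = tree.query_ball_point(cells.cell_xy, r)
    for ci, cand in enumerate(hits):
        if not cand:
            unassigned.append(ci)
            continue
        cand = sorted(cand)
        d = np.linalg.norm(sc.spot_xy[cand] - cells.cell_xy[ci], axis=1)
        best = cand[int(np.argmin(d))]  # argmin keeps first (lowest index) on ties
        members.setdefault(best, []).append(ci)
    bags = BagAssignment({s: np.array(v, dtype=np.int64) for s, v in members.items()})
    return bags, np.array(unassigned, dtype=np.int64)
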