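"""Evaluation metrics, marker-gene signature scoring and group-wise ranking.

Correlations are reported per gene across observations (spots or cells):
Pearson (product-moment) for linear association and Spearman (Pearson on
average ranks) for monotone association, alongside root-mean-squared error
and mean absolute error.  Genes whose truth or prediction is constant have
an undefined correlation; they are recorded as missing and excluded from
summary means rather than silently counted as zero.  Summary uncertainty is
a percentile bootstrap over genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CellPrediction


@dataclass
class MetricsReport:
    per_gene: pd.DataFrame  # gene_id, pcc, scc, rmse, mae (NaN where undefined)
    level: str  # "spot" | "cell"
    summary: dict  # mean of each metric over defined genes
    ci: dict  # metric -> (low, high) 95% bootstrap interval, filled by caller
    n_excluded: int  # genes dropped from correlation summaries (constant columns)


@dataclass
class MarkerGeneSet:
    cell_type: str
    markers: list
    controls: list | None = None  # explicit control genes, or None to bin-match

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker gene list must be non-empty")


def compute_metrics(
    pred: np.ndarray,
    truth: np.ndarray,
    level: str = "spot",
    gene_ids: list | None = None,
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Per-gene PCC / SCC / rMSE / MAE between prediction and truth columns.

    Truth is expected on the log-normalised scale for correlation reporting.
    Requires at least 3 observations.
    """
    P = np.asarray(pred, float)
    T = np.asarray(truth, float)
    if P.shape != T.shape:
        raise ValueError(f"shape mismatch {P.shape} vs {T.shape}")
    n, G = P.shape
    if n < 3:
        raise ValueError("need at least 3 observations per gene")
    gids = [f"g{j}" for j in range(G)] if gene_ids is None else list(gene_ids)

    pcc = np.full(G, np.nan)
    scc = np.full(G, np.nan)
    defined = (P.std(axis=0) > 0) & (T.std(axis=0) > 0)
    for j in np.where(defined)[0]:
        pcc[j] = stats.pearsonr(P[:, j], T[:, j]).statistic
        scc[j] = stats.spearmanr(P[:, j], T[:, j]).statistic
    rmse = np.sqrt(np.mean((P - T) ** 2, axis=0))
    mae = np.mean(np.abs(P - T), axis=0)

    per_gene = pd.DataFrame(
        {"gene_id": gids, "pcc": pcc, "scc": scc, "rmse": rmse, "mae": mae}
    )
    summary = {
        "pcc": float(np.nanmean(pcc)) if defined.any() else float("nan"),
        "scc": float(np.nanmean(scc)) if defined.any() else float("nan"),
        "rmse": float(rmse.mean()),
        "mae": float(mae.mean()),
    }
    ci = {}
    for metric in ("pcc", "scc", "rmse", "mae"):
        vals = per_gene[metric].dropna().to_numpy()
        if len(vals) >= 2:
            ci[metric] = bootstrap_ci(vals, n_boot=n_boot, seed=seed)
    return MetricsReport(
        per_gene=per_gene,
        level=level,
        summary=summary,
        ci=ci,
        n_excluded=int((~defined).sum()),
    )


def bootstrap_ci(
    values: np.ndarray, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of per-gene values."""
    vals = np.asarray(values, float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Signature scoring
# ---------------------------------------------------------------------------

def score_cells(
    pred: CellPrediction,
    ms: MarkerGeneSet,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Signature score per cell: mean over markers minus mean over controls.

    Pipeline: (1) scale every cell to the same total expression (the median
    total); (2) standardise each gene; (3) when no explicit control list is
    given, draw control genes matched on mean expression — genes are cut
    into ``n_bins`` by mean, and ``n_ctrl`` controls are sampled (seeded)
    from the bin of each marker, excluding the markers themselves;
    (4) ``s_m = mean over G_m - mean over G_c`` of the standardised values.
    """
    gene_index = {g: j for j, g in enumerate(pred.gene_ids)}
    missing = [g for g in ms.markers if g not in gene_index]
    if missing:
        raise ValueError(f"marker genes absent from prediction: {missing}")

    X = np.asarray(pred.scores, float)
    totals = X.sum(axis=1)
    target = np.median(totals[totals > 0]) if np.any(totals > 0) else 1.0
    safe = np.where(totals > 0, totals, 1.0)
    Xn = X / safe[:, None] * target

    mean_g = Xn.mean(axis=0)
    sd_g = Xn.std(axis=0)
    sd_g = np.where(sd_g == 0, 1.0, sd_g)
    Z = (Xn - mean_g) / sd_g

    m_idx = np.array([gene_index[g] for g in ms.markers])
    if ms.controls is not None:
        missing_c = [g for g in ms.controls if g not in gene_index]
        if missing_c:
            raise ValueError(f"control genes absent from prediction: {missing_c}")
        c_idx = np.array([gene_index[g] for g in ms.controls])
    else:
        # expression-bin-matched control pool
        order = np.argsort(mean_g, kind="stable")
        bins = np.empty(len(mean_g), dtype=np.int64)
        bins[order] = np.arange(len(mean_g)) * n_bins // len(mean_g)
        rng = np.random.default_rng(seed)
        marker_set = set(m_idx.tolist())
        chosen: set[int] = set()
        for mi in m_idx:
            # widen to neighbouring bins when a bin holds only marker genes
            for width in range(n_bins + 1):
                lo, hi = bins[mi] - width, bins[mi] + width
                pool = np.where((bins >= lo) & (bins <= hi))[0]
                pool = np.array([p for p in pool if p not in marker_set])
                if len(pool):
                    break
            if len(pool) == 0:
                continue
            take = min(n_ctrl, len(pool))
            chosen.update(rng.choice(pool, size=take, replace=False).tolist())
        if not chosen:
            raise ValueError("no control genes available outside the marker list")
        c_idx = np.array(sorted(chosen))
    return Z[:, m_idx].mean(axis=1) - Z[:, c_idx].mean(axis=1)


# ---------------------------------------------------------------------------
# Group-wise differential ranking
# ---------------------------------------------------------------------------

def rank_genes_by_group(
    pred: np.ndarray,
    labels: np.ndarray,
    gene_ids: list | None = None,
    eps: float = 1e-9,
) -> dict[str, pd.DataFrame]:
    """Welch t statistic of each gene, one group against the rest.

    ``t = (mean_g - mean_rest) / sqrt(var_g/n_g + var_rest/n_rest)``; genes
    are ranked by descending t per group, with two-sided p-values from the
    Welch-Satterthwaite degrees of freedom.  Zero pooled variance is guarded
    by ``eps``.
    """
    X = np.asarray(pred, float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    G = X.shape[1]
    gids = [f"g{j}" for j in range(G)] if gene_ids is None else list(gene_ids)
    out: dict[str, pd.DataFrame] = {}
    for g in groups:
        sel = labels == g
        n1, n2 = int(sel.sum()), int((~sel).sum())
        if n1 < 2 or n2 < 2:
            raise ValueError(f"group {g!r} needs >= 2 cells on both sides")
        m1, m2 = X[sel].mean(axis=0), X[~sel].mean(axis=0)
        v1, v2 = X[sel].var(axis=0, ddof=1), X[~sel].var(axis=0, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(np.maximum(se2, eps))
        df = np.maximum(
            se2 ** 2
            / np.maximum(
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1), eps ** 2
            ),
            1.0,
        )
        p = 2 * stats.t.sf(np.abs(t), df)
        tab = pd.DataFrame({"gene_id": gids, "t": t, "pval": p})
        out[str(g)] = tab.sort_values(
            ["t", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return out


def top_cells(scores: np.ndarray, cell_ids: np.ndarray, n: int = 100) -> np.ndarray:
    """Ids of the ``n`` highest-scoring cells (descending; ties by ascending id)."""
    scores = np.asarray(scores, float)
    ids = np.asarray(cell_ids, dtype=object)
    order = np.lexsort((ids, -scores))
    return ids[order[: min(n, len(ids))]]


def minmax_per_gene(values: np.ndarray) -> np.ndarray:
    """Per-gene (column) min-max scaling to [0, 1]; constant genes map to 0."""
    X = np.asarray(values, float)
    if X.size == 0:
        raise ValueError("empty input")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span)
    return (X - lo) / span
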