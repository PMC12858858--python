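"""Multiple-instance regression of gene expression from cell embeddings.

A spot is a bag, its cells are instances.  An instance-level scorer
``f_theta`` (feed-forward net: input d -> 256 -> 256 -> 256 -> G, ReLU hidden
activations, softplus output so every predicted score is non-negative) maps
each cell embedding to a vector of gene scores; a mean over the ``k_s``
member cells gives the spot-level prediction that is compared with the
measured spot expression.

Two objectives are supported:

* ``mse`` — mean squared error on library-size log-normalised expression,
  with each gene additionally scaled (divided by its interquartile range,
  slide by slide) so that all genes contribute comparably to the loss.  The
  IQR scaling deliberately omits median-centring: a softplus output is
  non-negative, and centred targets would be unreachable for half the spots.
* ``nb_nll`` — negative log-likelihood of the raw counts under a negative
  binomial with mean ``l_i * yhat_ij`` and gene-wise learned inverse
  overdispersion ``alpha_j`` (variance ``mu + mu^2/alpha``); ``l_i`` is the
  spot library size divided by the median training library size, so library
  depth is not absorbed into the cell scores.

Optimisation follows the AdamW recipe (lr 1e-4, batches of 128 bags) with a
20 %% held-out validation split and early stopping (patience 20 epochs); the
weights from the best validation epoch are restored before returning.
The whole stack is plain numpy with hand-written backpropagation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import digamma, gammaln

from .core_io import BagAssignment, CellPrediction, EmbeddingMatrix, SpotCounts, derive_seed
from .preprocess import lognormalize, robust_scale

_HIDDEN = 256
_N_HIDDEN_LAYERS = 3


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 128
    weight_decay: float = 0.01
    val_fraction: float = 0.20
    patience: int = 20
    max_epochs: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class LibraryFactors:
    """Per-spot library size divided by the median training library size."""

    l: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        if np.any(self.l <= 0):
            raise ValueError("library factors must be positive")

    @classmethod
    def from_counts(cls, counts: np.ndarray, train_rows: np.ndarray) -> "LibraryFactors":
        lib = np.asarray(counts).sum(axis=1).astype(float)
        med = np.median(lib[np.asarray(train_rows)])
        if med <= 0:
            raise ValueError("median training library size is zero")
        return cls(l=lib / med)


@dataclass
class MILModel:
    """A trained instance-level scorer plus its loss configuration."""

    params: dict
    loss_kind: str
    gene_ids: np.ndarray
    input_dim: int
    scaler_params: dict | None = None
    slide_id: str = "slide"
    encoder_tag: str = "external"
    train_config: TrainConfig | None = None

    @property
    def alpha(self) -> np.ndarray | None:
        """Gene-wise inverse overdispersion (nb_nll models only)."""
        if "log_alpha" not in self.params:
            return None
        return np.exp(self.params["log_alpha"])


# ---------------------------------------------------------------------------
# Network primitives
# ---------------------------------------------------------------------------

def _init_params(rng: np.random.Generator, d_in: int, d_out: int) -> dict:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) init for weights and biases."""
    dims = [d_in] + [_HIDDEN] * _N_HIDDEN_LAYERS + [d_out]
    params: dict = {}
    for i in range(len(dims) - 1):
        bound = 1.0 / np.sqrt(dims[i])
        params[f"W{i}"] = rng.uniform(-bound, bound, size=(dims[i], dims[i + 1]))
        params[f"b{i}"] = rng.uniform(-bound, bound, size=dims[i + 1])
    return params


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def _forward(params: dict, X: np.ndarray, cache: bool = False):
    acts = [X]
    h = X
    n_layers = _N_HIDDEN_LAYERS + 1
    for i in range(n_layers):
        z = h @ params[f"W{i}"] + params[f"b{i}"]
        h = np.maximum(z, 0.0) if i < n_layers - 1 else _softplus(z)
        if cache:
            acts.append(z)
            acts.append(h)
    return (h, acts) if cache else h


def _backward(params: dict, acts: list, dOut: np.ndarray) -> dict:
    """Gradients of a scalar loss wrt every parameter, given dLoss/dOutput."""
    grads: dict = {}
    n_layers = _N_HIDDEN_LAYERS + 1
    # acts layout: [X, z0, h0, z1, h1, z2, h2, z3, out]
    dh = dOut
    for i in reversed(range(n_layers)):
        z = acts[1 + 2 * i]
        h_prev = acts[2 * i] if i == 0 else acts[2 * i]
        if i == n_layers - 1:
            dz = dh * _sigmoid(z)  # d softplus
        else:
            dz = dh * (z > 0)
        grads[f"W{i}"] = h_prev.T @ dz
        grads[f"b{i}"] = dz.sum(axis=0)
        if i > 0:
            dh = dz @ params[f"W{i}"].T
    return grads


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _AdamW:
    """Decoupled weight decay Adam; decay applied to weight matrices only."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            if self.wd and k.startswith("W"):
                params[k] -= self.lr * self.wd * params[k]
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Aggregation and losses
# ---------------------------------------------------------------------------

def aggregate_bag(instance_preds: np.ndarray) -> np.ndarray:
    """Mean over the bag's instances (permutation invariant by construction)."""
    instance_preds = np.asarray(instance_preds, dtype=float)
    if instance_preds.ndim != 2 or instance_preds.shape[0] == 0:
        raise ValueError("bag must contain at least one instance row")
    return instance_preds.mean(axis=0)


def mse_loss(pred_spot: np.ndarray, target_scaled: np.ndarray) -> float:
    """Mean squared difference over all S*G entries."""
    pred_spot = np.asarray(pred_spot, float)
    target_scaled = np.asarray(target_scaled, float)
    if pred_spot.shape != target_scaled.shape:
        raise ValueError(
            f"shape mismatch {pred_spot.shape} vs {target_scaled.shape}"
        )
    return float(np.mean((pred_spot - target_scaled) ** 2))


def _nb_log_pmf(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative binomial log pmf, mean / inverse-overdispersion parametrisation.

    ``Var = mu + mu^2 / alpha``; the Poisson limit is recovered as
    ``alpha -> inf``.
    """
    mu = np.maximum(mu, 1e-12)
    return (
        gammaln(y + alpha)
        - gammaln(alpha)
        - gammaln(y + 1.0)
        + alpha * (np.log(alpha) - np.log(alpha + mu))
        + y * (np.log(mu) - np.log(alpha + mu))
    )


def nb_nll_loss(
    pred_mean: np.ndarray,
    counts: np.ndarray,
    alpha: np.ndarray,
    l: LibraryFactors | np.ndarray,
) -> float:
    """Negative log-likelihood of counts, summed over genes, averaged over spots.

    The mean of entry (i, j) is ``l_i * pred_mean_ij``.
    """
    counts = np.asarray(counts, dtype=float)
    if not np.allclose(counts, np.round(counts)) or np.any(counts < 0):
        raise ValueError("counts must be non-negative integers")
    lv = l.l if isinstance(l, LibraryFactors) else np.asarray(l, float)
    mu = lv[:, None] * np.asarray(pred_mean, float)
    lp = _nb_log_pmf(counts, mu, np.asarray(alpha, float)[None, :])
    return float(-lp.sum() / counts.shape[0])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batch_forward_spot(params, E, bag_members, bag_sizes):
    """Forward all instances of a batch of bags; return spot means + cache."""
    idx = np.concatenate(bag_members)
    X = E[idx]
    out, acts = _forward(params, X, cache=True)
    starts = np.concatenate([[0], np.cumsum(bag_sizes)[:-1]])
    spot_pred = np.add.reduceat(out, starts, axis=0) / np.asarray(bag_sizes)[:, None]
    return spot_pred, out, acts, np.asarray(bag_sizes)


def _spread_spot_grad(d_spot, bag_sizes):
    """d loss / d instance output, given d loss / d spot mean."""
    per_instance = d_spot / bag_sizes[:, None]
    return np.repeat(per_instance, bag_sizes, axis=0)


def _softplus_inverse(y: np.ndarray) -> np.ndarray:
    y = np.maximum(np.asarray(y, float), 1e-6)
    return np.where(y > 30, y, np.log(np.expm1(np.minimum(y, 30.0))))


def _fit(
    E: np.ndarray,
    bag_members: list[np.ndarray],
    targets: np.ndarray,
    counts: np.ndarray | None,
    lib: np.ndarray | None,
    cfg: TrainConfig,
    loss_kind: str,
    G: int,
):
    """Shared optimisation loop over bags; returns (params, history)."""
    n_bags = len(bag_members)
    rng_split = np.random.default_rng(derive_seed(cfg.seed, "split"))
    perm = rng_split.permutation(n_bags)
    n_val = max(1, int(round(cfg.val_fraction * n_bags)))
    if n_val >= n_bags:
        raise ValueError("validation split leaves no training bags")
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    rng_init = np.random.default_rng(derive_seed(cfg.seed, "init"))
    params = _init_params(rng_init, E.shape[1], G)
    # start the net at the per-gene marginal level (base-rate initialisation):
    # the output bias is set so softplus(bias) equals the mean training
    # target, leaving only O(1) deviations for the optimiser to learn
    if loss_kind == "mse":
        level = targets[train_idx].mean(axis=0)
    else:
        level = (counts[train_idx] / lib[train_idx][:, None]).mean(axis=0)
    params[f"b{_N_HIDDEN_LAYERS}"] = _softplus_inverse(level)
    if loss_kind == "nb_nll":
        params["log_alpha"] = np.zeros(G)  # alpha initialised at 1
    opt = _AdamW(params, cfg.learning_rate, cfg.weight_decay)

    def eval_loss(idx_set: np.ndarray) -> float:
        members = [bag_members[i] for i in idx_set]
        sizes = [len(m) for m in members]
        spot_pred, *_ = _batch_forward_spot(params, E, members, sizes)
        if loss_kind == "mse":
            return mse_loss(spot_pred, targets[idx_set])
        alpha = np.exp(params["log_alpha"])
        mu = lib[idx_set][:, None] * np.maximum(spot_pred, 1e-12)
        lp = _nb_log_pmf(counts[idx_set], mu, alpha[None, :])
        return float(-lp.sum() / len(idx_set))

    history = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_val = np.inf
    best_params: dict | None = None
    since_improve = 0
    rng_shuffle = np.random.default_rng(derive_seed(cfg.seed, "shuffle"))

    for epoch in range(cfg.max_epochs):
        order = rng_shuffle.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            members = [bag_members[i] for i in batch]
            sizes = [len(m) for m in members]
            spot_pred, out, acts, sizes_arr = _batch_forward_spot(
                params, E, members, sizes
            )
            B = len(batch)
            if loss_kind == "mse":
                diff = spot_pred - targets[batch]
                loss = float(np.mean(diff ** 2))
                d_spot = 2.0 * diff / diff.size
                extra_grads = {}
            else:
                alpha = np.exp(params["log_alpha"])
                mu = lib[batch][:, None] * np.maximum(spot_pred, 1e-12)
                y = counts[batch]
                lp = _nb_log_pmf(y, mu, alpha[None, :])
                loss = float(-lp.sum() / B)
                dmu = ((y + alpha[None, :]) / (alpha[None, :] + mu) - y / np.maximum(mu, 1e-12)) / B
                d_spot = dmu * lib[batch][:, None]
                dl_dalpha = -(
                    digamma(y + alpha[None, :])
                    - digamma(alpha[None, :])
                    + np.log(alpha[None, :])
                    - np.log(alpha[None, :] + mu)
                    + 1.0
                    - (y + alpha[None, :]) / (alpha[None, :] + mu)
                ) / B
                extra_grads = {"log_alpha": (dl_dalpha * alpha[None, :]).sum(axis=0)}
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            d_out = _spread_spot_grad(d_spot, sizes_arr)
            grads = _backward(params, acts, d_out)
            grads.update(extra_grads)
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        val_loss = eval_loss(val_idx)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            history["best_epoch"] = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience:
                break
    if best_params is not None:
        params = best_params
    return params, history


def train(
    bags: BagAssignment,
    E: EmbeddingMatrix,
    sc: SpotCounts,
    cfg: TrainConfig,
    loss_kind: str = "mse",
    *,
    scale_targets: bool = True,
    center_targets: bool = False,
) -> tuple[MILModel, dict]:
    """Train the MIL regressor on spot-level supervision.

    For ``mse`` the targets are log-normalised spot vectors, per-gene
    IQR-scaled with parameters fitted on the training split; for ``nb_nll``
    the targets are raw counts with library factors computed on the training
    split only.  Returns the model restored to its best validation epoch and
    the per-epoch loss history.
    """
    if loss_kind not in ("mse", "nb_nll"):
        raise ValueError(f"unknown loss {loss_kind!r}")
    spots = bags.spots()
    if len(spots) < 2:
        raise ValueError("need at least 2 spots with assigned cells")
    if E.n_cells <= max((int(m.max()) for m in bags.spot_to_cells.values() if len(m)), default=-1):
        raise ValueError("bag refers to a cell index beyond the embedding matrix")
    bag_members = [bags.spot_to_cells[s] for s in spots]
    counts = sc.counts[spots].astype(float)

    # reproduce the eventual training split to fit target statistics on it only
    rng_split = np.random.default_rng(derive_seed(cfg.seed, "split"))
    perm = rng_split.permutation(len(spots))
    n_val = max(1, int(round(cfg.val_fraction * len(spots))))
    train_rows = perm[n_val:]

    scaler = None
    lib = None
    raw = None
    if loss_kind == "mse":
        logn = lognormalize(counts)
        if scale_targets:
            _, scaler = robust_scale(
                logn[train_rows],
                np.full(len(train_rows), sc.slide_id, dtype=object),
                with_centering=center_targets,
            )
            center, spread = scaler[sc.slide_id]
            targets = (logn - center) / spread
        else:
            targets = logn
    else:
        targets = np.zeros_like(counts)
        raw = counts
        lib = LibraryFactors.from_counts(counts, train_rows).l

    params, history = _fit(
        E.values, bag_members, targets, raw, lib, cfg, loss_kind, sc.n_genes
    )
    model = MILModel(
        params=params,
        loss_kind=loss_kind,
        gene_ids=sc.gene_ids,
        input_dim=E.dim,
        scaler_params=scaler,
        slide_id=sc.slide_id,
        encoder_tag=E.encoder_tag,
        train_config=cfg,
    )
    return model, history


def train_supervised(
    E_cells: EmbeddingMatrix,
    Y_cells: np.ndarray,
    cfg: TrainConfig,
    gene_ids: np.ndarray | None = None,
    *,
    scale_targets: bool = True,
    center_targets: bool = False,
) -> tuple[MILModel, dict]:
    """Fully supervised upper-bound baseline (simulation only).

    Same architecture, optimiser and early stopping as :func:`train`, but
    with per-cell log-normalised expression as the target (each cell is a
    bag of one).
    """
    Y = np.asarray(Y_cells, dtype=float)
    keep = Y.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-total cells", stacklevel=2)
    Y = Y[keep]
    X = E_cells.values[keep]
    logn = lognormalize(Y)

    rng_split = np.random.default_rng(derive_seed(cfg.seed, "split"))
    perm = rng_split.permutation(len(Y))
    n_val = max(1, int(round(cfg.val_fraction * len(Y))))
    train_rows = perm[n_val:]

    scaler = None
    if scale_targets:
        _, scaler = robust_scale(
            logn[train_rows],
            np.full(len(train_rows), "cells", dtype=object),
            with_centering=center_targets,
        )
        center, spread = scaler["cells"]
        targets = (logn - center) / spread
    else:
        targets = logn

    members = [np.array([i]) for i in range(len(Y))]
    params, history = _fit(X, members, targets, None, None, cfg, "mse", Y.shape[1])
    G = Y.shape[1]
    gids = (
        np.array([f"g{i}" for i in range(G)], dtype=object)
        if gene_ids is None
        else np.asarray(gene_ids, dtype=object)
    )
    model = MILModel(
        params=params,
        loss_kind="mse",
        gene_ids=gids,
        input_dim=X.shape[1],
        scaler_params=scaler,
        slide_id="cells",
        encoder_tag=E_cells.encoder_tag,
        train_config=cfg,
    )
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_cells(
    model: MILModel, E: EmbeddingMatrix, *, invert_scaling: bool = True
) -> CellPrediction:
    """Apply the instance scorer row-wise; outputs are non-negative.

    When the MSE pathway scaled its targets and ``invert_scaling`` is on,
    the stored per-gene spread (and centre, if any) is inverted so the scores
    land back on the log-normalised scale.
    """
    if E.dim != model.input_dim:
        raise ValueError(
            f"embedding dim {E.dim} does not match model input {model.input_dim}"
        )
    out = _forward(model.params, E.values)
    if invert_scaling and model.loss_kind == "mse" and model.scaler_params:
        # single training slide: one (center, spread) pair applies to all cells
        center, spread = next(iter(model.scaler_params.values()))
        out = np.maximum(out * spread + center, 0.0)
    return CellPrediction(scores=out, gene_ids=model.gene_ids, cell_ids=E.cell_ids)


def predict_spots(
    model: MILModel,
    bags: BagAssignment,
    E: EmbeddingMatrix,
    *,
    invert_scaling: bool = True,
) -> tuple[list[int], np.ndarray]:
    """Spot-level predictions: bag means of the instance predictions.

    Returns (spot indices, S x G matrix); empty bags are skipped with a
    warning.
    """
    pred = predict_cells(model, E, invert_scaling=invert_scaling)
    spots = []
    rows = []
    for s in bags.spots():
        members = bags.spot_to_cells[s]
        if len(members) == 0:
            warnings.warn(f"spot {s} has an empty bag; skipped", stacklevel=2)
            continue
        spots.append(s)
        rows.append(aggregate_bag(pred.scores[members]))
    return spots, np.vstack(rows) if rows else np.zeros((0, len(model.gene_ids)))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_model(model: MILModel, path: str | Path) -> None:
    """Single-file archive: weights + gene ids + scaler + config."""
    meta = {
        "loss_kind": model.loss_kind,
        "input_dim": model.input_dim,
        "slide_id": model.slide_id,
        "encoder_tag": model.encoder_tag,
        "gene_ids": [str(g) for g in model.gene_ids],
        "train_config": asdict(model.train_config) if model.train_config else None,
        "scaler_slides": list(model.scaler_params) if model.scaler_params else [],
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    if model.scaler_params:
        for slide, (center, spread) in model.scaler_params.items():
            arrays[f"scaler_center_{slide}"] = center
            arrays[f"scaler_spread_{slide}"] = spread
    np.savez(Path(path), meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> MILModel:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        params = {
            k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")
        }
        scaler = None
        if meta["scaler_slides"]:
            scaler = {
                s: (z[f"scaler_center_{s}"], z[f"scaler_spread_{s}"])
                for s in meta["scaler_slides"]
            }
    cfg = TrainConfig(**meta["train_config"]) if meta["train_config"] else None
    return MILModel(
        params=params,
        loss_kind=meta["loss_kind"],
        gene_ids=np.array(meta["gene_ids"], dtype=object),
        input_dim=int(meta["input_dim"]),
        scaler_params=scaler,
        slide_id=meta["slide_id"],
        encoder_tag=meta["encoder_tag"],
        train_config=cfg,
    )
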