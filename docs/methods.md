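# Methods

## Problem and model

Sequencing-based spatial transcriptomics (Visium-style) measures gene
expression at barcoded capture spots of ~55 µm that each contain on the
order of 10–20 cells. `spotmil` learns a *cell-level* expression predictor
from this *spot-level* supervision, given only a per-cell embedding vector
(typically derived from an H&E image crop of the cell by a pretrained
encoder; the encoder itself is out of scope and any N×d matrix aligned to
the cell table is accepted).

The training problem is cast as multiple-instance regression. A spot `s` is
a bag holding the `k_s` cells linked to it (a cell is linked to the nearest
spot centre within the spot radius; boundary inclusive, ties to the lower
spot index). An instance scorer `f_θ` — a fully connected network, input
`d` → three hidden layers of 256 (ReLU) → `G` outputs through a softplus —
maps each member cell's embedding `h_i` to a non-negative gene-score
vector. The spot prediction is the mean over the bag,

    ŷ_s = (1/k_s) · Σ_{i=1..k_s} f_θ(h_i),

which emulates the physical measurement (a spot's counts are the pooled
transcripts of its cells) and is permutation invariant. After training,
`f_θ` applied to single cells yields cell-level expression scores.

## Objectives

**MSE on normalised expression (default).** Spot counts are library-size
normalised and log-transformed, `y^p_j = ln(1 + s·y_j/Σ_j y_j)` with
`s = 10 000`, then each gene is scaled to a similar range by dividing by
its interquartile range (per gene, per slide, fitted on the training split;
zero-IQR genes are divided by 1). The loss is the plain mean of squared
differences over all spot×gene entries.

The scaling deliberately does *not* subtract the per-gene median, although
that is what a stock robust scaler would do (and the library's general
`robust_scale` function defaults to the centred form). The reason is a
representability constraint: the scorer ends in a softplus, so predictions
are non-negative, while median-centred targets are negative for roughly
half the spots whenever a gene's median expression is well above zero. On
dense data this puts a hard floor under the training loss — in our centroid
simulations the fit saturates far below the linear-model ceiling — whereas
pure IQR scaling keeps every target non-negative and reachable. (On very
sparse genes, whose median is zero, the two choices coincide, which is why
centred scaling is harmless in the sparse-gene regime.) Predictions are
mapped back to the log-normalised scale by the stored inverse transform
(toggleable via `invert_scaling`).

**Negative-binomial likelihood on raw counts.** Alternatively the scorer
output is read as the NB mean: entry `(i, j)` has mean `l_i · ŷ_ij` with
`l_i` the spot's library size divided by the median training library size
(so depth is not absorbed into cell scores), and gene-specific inverse
overdispersion `α_j` (variance `μ + μ²/α`), learned as `exp` of a free
parameter initialised at 1. The loss is the negative log pmf summed over
genes and averaged over spots. Poisson behaviour is recovered as
`α → ∞`.

## Optimisation

AdamW (β = 0.9/0.999, ε = 1e-8, decoupled weight decay 0.01 applied to
weight matrices only), learning rate 1e-4, batches of 128 bags, at most
400 epochs by default. 20 % of spots are held out (bags are atomic, so a
spot's cells never straddle the split); after each epoch the validation
loss is evaluated and training stops once it has not improved for 20
epochs, restoring the weights of the best epoch.

Weights and biases are initialised uniformly in ±1/√fan_in. The output
bias is then overwritten with `softplus⁻¹` of the per-gene mean training
target (base-rate initialisation): the network starts as the marginal
per-gene predictor and only has to learn deviations around it. Without
this, Adam at lr 1e-4 spends thousands of steps climbing the per-gene
levels (which IQR-only scaling can inflate by 1/IQR), and early stopping
can trigger long before convergence.

All numerics are plain numpy with hand-written backpropagation; the NB
gradient uses the digamma form of `∂ log pmf/∂α`. Every random choice
(split, init, shuffling, sampling, bootstrap) draws from a named child
seed derived from one root seed, so repeated runs are bit-identical.

The fully supervised baseline shares the architecture, optimiser and
early-stopping protocol but regresses per-cell log-normalised expression
(each cell a bag of one); it is only available in simulations, where
per-cell ground truth exists.

## Preprocessing

Genes are kept if their slide total is ≥ 200 counts and they are detected
in ≥ 10 % of (training) spots; spots are kept if they have ≥ 1 linked cell
and ≥ 20 counts. Gene panels come from either highly variable genes —
per-batch standardised variance after a lowess mean-variance trend
correction (clip at √N), aggregated across batches by top-n membership and
median rank, so slide-specific genes are not favoured — or spatially
variable genes, ranked by Moran's I computed per slide on log-normalised
values with a symmetrised binary k-nearest-neighbour weight matrix (k = 6,
the hexagonal neighbourhood of a Visium array; not row-normalised).
Because Moran's I lies in [−1, 1], per-slide scores are shifted by +1
before the across-slide geometric mean; the shift is order-preserving on a
single slide and keeps the geometric mean defined when autocorrelation is
negative.

Quantiles use linear interpolation throughout.

## Simulation framework

The simulation assigns expression to cells with a controlled degree of
coupling to their embeddings. Morphology clusters are found by k-means
(k = 6, k-means++ init, best of 10 restarts) on the cell embeddings; the
2000 cells nearest each centroid are retained; morphology clusters are
matched to reference clusters by a seeded arbitrary bijection. Expression
is then assigned per scenario — `random`: any reference cell, ignoring
clusters; `centroid`: the matched cluster's mean profile; `cell`: a random
cell of the matched cluster — and spots are formed by drawing member cells
(with replacement across spots, without replacement within a spot; each
draw is materialised as its own cell instance) and summing their counts
exactly. Train and test sets are sampled independently with derived seeds
under a shared cluster matching. Gene lists (HVGs, markers) are always
computed on the reference, never on simulated spots, so all scenarios use
one panel.

In the centroid scenario the cluster-mean profile is rounded to the
nearest integer so that counts stay integral end to end; genes whose
rounded profiles coincide across all clusters become constant and are
reported as excluded from correlation summaries rather than scored.

**Synthetic reference.** A clustered single-cell reference is generated
rather than downloaded: per-gene base means are log-normal (median 0.5
counts per cell, σ_log = 1 — a skewed mean distribution typical of
single-cell panels), counts are negative binomial with inverse
overdispersion 2, and each cluster's designated marker genes (5 per
cluster by default) have their mean multiplied by a fold change of 5 in
that cluster only. Defaults: K = 6 clusters, G = 300 genes, 500 cells per
cluster. What this emulates: cluster structure, marker enrichment,
overdispersed counts, skewed mean distribution. What it does not: the
mean-variance trend of a real atlas, batch effects, ambient RNA, gene-gene
correlation beyond cluster membership, or realistic whole-transcriptome
sparsity. Consequently, passing simulation tests demonstrates that the
weak-supervision machinery recovers morphology-linked expression under
controlled coupling; it does not certify accuracy on real slides, which
additionally depends on encoder quality and on how much expression
variation is visible in morphology.

Simulated geometry places spots on a square grid (spacing 150 px, radius
50 px) with member cells scattered inside the capture disc, so the
linkage, IO and CLI paths run on simulated bundles unchanged.

## Evaluation and downstream analysis

Metrics are computed per gene across spots (or cells): Pearson and
Spearman correlation (average ranks on ties), rMSE and MAE, with
correlations of constant columns recorded as missing, excluded from the
summary mean and counted. Summary uncertainty is a 95 % percentile
bootstrap over genes (1000 resamples, seeded).

Marker-gene signature scores per cell follow: scale every cell to the
median total; standardise each gene; controls either given explicitly or
drawn seeded from mean-expression-matched bins (25 bins, 50 controls per
marker bin, markers excluded; a bin containing only markers is widened to
its neighbours); score = mean over markers − mean over controls.
Group-wise gene ranking uses the Welch t statistic (one group vs rest,
two-sided p from Welch–Satterthwaite df, zero-variance guard ε = 1e-9).
Galleries are the top-100 cells by score (ties to the lower cell id), and
per-gene min-max scaling maps constant genes to 0.

## Problem sizes used in the shipped checks

The automated checks run the full pipeline at desk scale: reference K = 6,
G = 300, 500 cells/cluster; random and centroid scenarios at 2000 spots ×
10 cells over a 15 000-cell pool (2000 kept per cluster, so the
nearest-to-centroid step genuinely trims); the cell scenario at 1000 spots
× 10 cells with a 6000-cell pool (1000 kept per cluster) over three seeds. These sizes were chosen so the
whole suite runs on a single CPU while keeping ≥ 10⁴ cell instances per
dataset; correlations at this scale are stable to ~0.01–0.03 across seeds.

## Known limitations

* One slide per training call; multi-slide training would need per-slide
  scaler bookkeeping in the model checkpoint (the scaler machinery already
  supports it).
* The NB pathway predicts mean counts; no inverse transform to the
  log-normalised scale is applied to its cell scores.
* k-means on near-duplicate embeddings can split clusters arbitrarily;
  the simulation relies on well-separated synthetic anchors.
* The supervised baseline requires per-cell ground truth and is therefore
  simulation-only by construction.
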