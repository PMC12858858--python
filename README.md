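# spotmil

Weakly supervised prediction of **single-cell** gene expression from
**spot-level** spatial transcriptomics.

Sequencing-based spatial transcriptomics (Visium-style) reports transcript
counts per barcoded *spot*, each covering roughly 10–20 cells, next to an
H&E image of the same section. Cell-resolved expression is never measured
directly. `spotmil` treats this as a multiple-instance regression problem:
each spot is a *bag*, the cells linked to it (nearest spot centre within
the spot radius) are its *instances*, and an instance-level scorer
`f_θ` — a feed-forward network (input `d` → 256 → 256 → 256 → `G`, softplus
output) — maps each cell's embedding `h_i ∈ R^d` to a non-negative vector
of gene scores. The spot-level prediction is the bag mean

```
ŷ_s = (1/k_s) Σ_{i=1..k_s} f_θ(h_i),
```

which is trained against the measured spot expression with either a mean
squared error on library-size log-normalised, per-gene IQR-scaled values
(`y^p_j = ln(1 + 104 · y_j / Σ_j y_j)`), or a negative-binomial likelihood
on raw counts with mean `l_i·ŷ_ij` (library factor `l_i`) and learned
gene-wise inverse overdispersion `α_j`. Applied to individual cells, the
trained scorer yields cell-level expression estimates from morphology
alone.

The package also ships the surrounding toolchain: readers/writers for the
MatrixMarket + sidecar bundles and positions tables, QC filters, HVG/SVG
gene selection (Moran's I with hexagonal k-NN weights), a simulation
framework with three morphology–expression coupling scenarios
(random / centroid / cell) plus a synthetic clustered single-cell
reference generator, per-gene evaluation metrics with bootstrap
confidence intervals, marker-gene signature scoring and group-wise
differential ranking. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

Simulate a centroid-scenario dataset (perfect morphology–expression
coupling), train the MIL regressor, and evaluate held-out spots:

```python
import numpy as np
from spotmil import (
    generate_reference, run_scenario, ScenarioConfig,
    TrainConfig, train, predict_spots, lognormalize, compute_metrics,
)

ref = generate_reference(K=6, G=300, cells_per_cluster=500,
                         fold_change=5.0, seed=0)
cfg = ScenarioConfig(scenario="centroid", n_spots=2000,
                     cells_per_spot=10, seed=0)
train_ds, test_ds = run_scenario(cfg, ref, one_hot=True)

model, hist = train(train_ds.bags, train_ds.embeddings,
                    train_ds.spot_counts, TrainConfig(seed=0))
spots, pred = predict_spots(model, test_ds.bags, test_ds.embeddings)
truth = lognormalize(test_ds.spot_counts.counts.astype(float))[spots]
report = compute_metrics(pred, truth, level="spot")
print(f"epochs run: {len(hist['val_loss'])}")
print(f"mean per-gene Pearson r: {report.summary['pcc']:.3f}")
print(f"genes excluded (constant): {report.n_excluded}")
```

```
epochs run: 175
mean per-gene Pearson r: 0.985
genes excluded (constant): 134
```

With a perfect morphology–expression link the bag-mean model recovers
spot expression almost exactly (the residual is the nonlinearity of
log-normalisation in the bag composition). Re-running with
`scenario="random"` — expression assigned independently of morphology —
gives a mean Pearson r of about 0.00: the model cannot (and should not)
predict expression that morphology does not determine. The excluded genes
are those whose simulated profiles are identical across all six clusters
and therefore constant across spots.

The same pipelines are scriptable from the shell:

```bash
spotmil simulate --scenario cell --k 6 --spots 5000 --cells-per-spot 20 \
    --seed 0 --out sim/
spotmil train --counts sim/train/spots --cells sim/train/cells.csv \
    --embeddings sim/train/embeddings.tsv --loss mse --seed 0 --out model.npz
spotmil predict --model model.npz --embeddings sim/test/embeddings.tsv --out pred/
spotmil evaluate --pred pred/ --truth sim/test/cell_expression.tsv \
    --level cell --boot 1000 --seed 0 --out report
```

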