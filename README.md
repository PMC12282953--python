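# momogp

Interpretable multi-output Gaussian-process latent variable models for
single-cell multi-omics.

## The problem

Single-cell experiments increasingly measure several molecular layers on the
same cells (RNA, chromatin accessibility, surface proteins).  Integration
methods usually learn one embedding of the *cells* and then interpret it by
clustering and differential expression — a post-hoc, cluster-resolution view
of which features drive which cells.  `momogp` instead models cells *and*
features jointly: every cell i and every feature j of every modality gets its
own latent coordinate, and observed values are a noisy draw from a GP over
(cell, feature) pairs,

    y_ij = f_ij + ε,   f ~ GP(0, k_A(a_i, a_i') · k_B(b_j, b_j')),

with ARD-RBF kernels k_A (cells) and k_B (features, one per modality) — a
Kronecker-structured multi-output GP whose "coregionalization" across
features is itself kernelized over a learned feature embedding.  Training
uses sparse stochastic variational inference over a triple store of
(i, j, y_ij) records with matched inducing pairs, so one epoch is linear in
the number of observed matrix entries.  In the multi-view model the cell
embedding is shared across modalities and each view carries its own ARD
weight vector w_v on the cell kernel (manifold relevance determination):
after training, dimensions with w_v above a small threshold δ in all views
are shared, in one view private, in none absent.

Because features live in their own latent space, interpretation is
clustering-free: feature clusters ("metagenes") come from the feature
embedding, and a *relevance map* — the gradient norm ‖∂μ_ij/∂a_i‖ of the GP
posterior mean with respect to a cell's coordinate, averaged over a
metagene — localizes the region of the cell embedding each metagene drives.
Thresholding the map (τ, in percent of the metagene's peak) links feature
groups to cell groups directly.

Audience: computational biologists and methodologists who want joint
cell/feature embeddings with explicit uncertainty semantics, on
log-normalized matrices of moderate size, without a GPU.

## Worked example

```python
import numpy as np
from momogp import (SimulationConfig, simulate, build_triple_store,
                    init_multi_model, TrainConfig, fit_multi,
                    evaluate_embedding, export_ard_report)

# two modalities over the same 300 cells, one private latent dim each + one shared
cfg = SimulationConfig(I=300, feature_counts=[50, 50], r1=3, r2=3,
                       feature_blocks=4, independent_dims=True,
                       activity=[[1, 1, 0], [0, 1, 1]], seed=0)
views, truth = simulate(cfg)
stores = [build_triple_store(v) for v in views]

model = init_multi_model(300, [50, 50], r1=3, r2=3, m=40, seed=0)
model = fit_multi(stores, TrainConfig(epochs=500, batch_size=2048,
                                      learning_rate=0.02, seed=0,
                                      analytic_q_every=75), model=model)

rep = evaluate_embedding(model.params["A"], truth.cell_cluster_labels, seed=0)
print(f"cell embedding: ACC {rep.acc:.1f}  ARI {rep.ari:.3f}")
print(export_ard_report(model))
```

prints (exact numbers from this seed):

```
cell embedding: ACC 99.0  ARI 0.979
            w_view0   w_view1          label
dimension
0          0.739782  0.000024  private_view0
1          0.000022  0.917130  private_view1
2          0.804710  0.771242         shared
```

ACC (the modal-label clustering accuracy, in percent) and ARI compare a
Gaussian-mixture clustering of the learned cell embedding with the
generative cluster labels; here the shared embedding recovers the cell
population structure almost perfectly.  The ARD table shows per-view weights
on the three cell-embedding dimensions: dimension 0 carries view-0 signal
only, dimension 1 view-1 signal only, and dimension 2 both — the model has
identified which axes of cell-state variation are modality-private and which
are common, matching how the data were generated
(`activity=[[1,1,0],[0,1,1]]` up to a permutation of dimensions).

The same pipeline runs from the shell:

```bash
momogp simulate --cells 300 --features 50,50 --seed 0 --out sim/
momogp fit --view rna=sim/view0 --view atac=sim/view1 \
           --latent-cells 3 --latent-feats 3 --inducing 40 \
           --epochs 500 --seed 0 --out ckpt/
momogp relevance --checkpoint ckpt/ --view rna --tau 30 --out interp/
momogp evaluate --checkpoint ckpt/ --labels sim/labels.tsv --out metrics.json
```

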