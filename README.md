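# stmask

Self-supervised spatial-domain embedding for spatial transcriptomics,
built on **dual-masked graph learning**: a masked graph autoencoder
(node-feature reconstruction) and masked-edge graph contrastive learning
share one GCN encoder and are optimised jointly. The learned spot
embeddings feed spatial-domain clustering, gene-expression denoising, and
multi-slice integration.

## Who it is for

Analysts of spot- or cell-resolved spatial expression data (Visium,
Stereo-seq, osmFISH, MERFISH, ST, ...) who want spatially coherent domain
assignments from a counts matrix plus (x, y) coordinates — no histology
image required — and who need the result to be deterministic per seed.

## The model

Spots form a K-nearest-neighbour graph on their coordinates
(`A`, symmetrised, no self-loops) with the normalised operator
`Â = D^{-1/2} A D^{-1/2}`. Two stochastic views are drawn each epoch:

* **Node masking** — a fraction `ρ_m` of spots has its feature row replaced
  by a learnable token; the encoder
  `H = Â · PReLU(BN(Â X_m W_g0)) · W_g1` (512 → 256) must infer them from
  neighbours. Masked latent rows are *re-masked* with a second token before
  the decoder `Z = Â · PReLU(BN(H̃ W_d0)) · W_d1` reconstructs the input.
  The loss is the scaled cosine error over masked spots,
  `L_SCE = mean (1 − cos(X_i, Z_i))^γ` with `γ = 2`.
* **Edge masking** — each graph edge is dropped with probability `ρ_d`; the
  *same* encoder reads `(X, Â_m)` and an MLP discriminator
  `D(h_i, h_j) = σ(w₂·ReLU(W₁(h_i ⊙ h_j) + b₁) + b₂)` must tell the dropped
  (positive) edges from sampled non-neighbour pairs (one negative per
  positive edge endpoint). The loss is a binary noise-contrastive
  estimation `L_NCE`.

The objective is `L = (1 − λ)·L_SCE + λ·L_NCE`, optimised by Adam
(lr 1e-3, weight decay 2e-4). Defaults: `ρ_m = 0.3`, `ρ_d = 0.4`,
`λ = 0.7`, `k = 6`. At inference the shared encoder embeds the unmasked
data; domains come from k-means on the embedding's top 30 PCs. The
denoising variant trains on the scaled highly-variable-gene matrix
(no PCA) and reads out the decoder reconstruction. Serial slices are
registered by rigid ICP, stacked along z at the spot pitch, and trained
jointly on a 3-D KNN graph; side-by-side slices are joined by edge-offset
translation. The network core is implemented in numpy with hand-written
backpropagation (finite-difference-verified in the test suite), so results
are bit-reproducible on CPU.

## Worked example

```python
import stmask
from stmask.train import TrainConfig, train, embed, cluster

ds, clean = stmask.simulate_slice(stmask.smoke_config())   # 30x30 grid, 4 domains
pre   = stmask.preprocess(ds)                              # filter/CPM/HVG/scale/PCA
graph = stmask.build_knn_graph(pre.coords, k=6)
state, trace = train(pre, graph, TrainConfig(epochs=300, seed=0))
labels = cluster(embed(pre, graph, state), n_clusters=4, seed=0).labels
print("ARI :", round(stmask.ari(labels, pre.truth), 3))
print("ACC :", round(stmask.acc(labels, pre.truth), 3))
print("DIS :", round(stmask.dis(labels, graph), 3))
```

prints

```
ARI : 0.934
ACC : 0.974
DIS : 0.07
```

ARI/ACC measure agreement with the planted domains (1 = perfect); DIS is
the fraction of spatial neighbours with discordant labels (0 = perfectly
coherent domains). For comparison, k-means on the raw top-30 principal
components of the same matrix reaches ARI 0.29 — the spatial graph and the
dual-masking objective contribute the rest.

The same workflow is available from the shell:

```bash
stmask simulate --preset smoke --out sim/
stmask run --counts sim/counts.csv --coords sim/coords.csv \
           --n-clusters 4 --epochs 300 --seed 0 --out run/
stmask eval --labels run/labels.csv --truth sim/truth.csv --coords sim/coords.csv
```

or through the sklearn-style estimators `stmask.DualMaskEmbedding`
(fit / transform / fit_predict) and `stmask.ExpressionDenoiser`.

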