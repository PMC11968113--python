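# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic generator does and does not emulate, and the
design decisions taken where the published description of this family of
methods leaves room.

## Preprocessing

The count pipeline is fixed-order: gene filter → spot filter → depth
normalisation → highly-variable-gene selection → per-gene scaling →
optional PCA.

* **Gene filter**: a gene is kept when it has a non-zero count in at least
  `min_spots_per_gene` spots (default 50). "Expressed in" is read as
  *detected* (non-zero), with no within-spot count threshold.
* **Spot filter**: applied after the gene filter; a spot is kept when its
  total count is at least `min_counts_per_spot` (default 10). The
  alternative reading — "a gene needs ≥ 10 counts within a spot to count as
  expressed" — was considered and rejected because a per-spot total filter
  keeps the subsequent depth normalisation well defined and matches common
  autoencoder-pipeline practice.
* **Normalisation**: every spot is scaled to a fixed total
  (`scale_target`, default 1e6). No log transform is applied — the model
  consumes z-scored depth-normalised values, and the scaled cosine loss is
  scale-invariant per spot.
* **HVG selection**: genes are ranked by dispersion (variance / mean) of
  the `log1p`-transformed normalised matrix and the top `n_hvg` (default
  2000) kept; panels at or below `n_hvg` genes pass through whole. A
  constant gene has zero dispersion and ranks last. This is a deliberately
  simple, deterministic dispersion flavour; binned variants (Seurat-style
  normalised dispersion) reorder marginal genes but not the strongly
  variable ones this model relies on.
* **Scaling**: per-gene z-score with the population (ddof = 0) standard
  deviation; zero-variance genes map to all-zero columns.
* **PCA**: exact SVD of the centred scaled matrix with a deterministic sign
  convention (each component's largest-magnitude loading is positive);
  output dimension `min(n_pca, n_genes, n_spots − 1)` with `n_pca = 200`.
  When the panel has fewer genes than `n_pca` (small imaging panels) the
  scaled matrix is passed through unchanged. The denoising configuration
  (`use_pca=False`) always feeds the scaled HVG matrix directly.

## Spatial graph

K-nearest neighbours on Euclidean coordinates, `k = 6` by default — the
first-shell neighbourhood of a hexagonally packed Visium array and a
reasonable local neighbourhood for grids; exact distance ties break toward
the smaller spot index so construction is deterministic. The directed
pick-lists are symmetrised by union (an edge exists if either endpoint
chose the other), which preserves connectivity at tissue boundaries. No
self-loops are added anywhere: the encoder's first and second layers both
premultiply by `Â = D^{-1/2} A D^{-1/2}`, so a spot's own (possibly
masked) features reach it only through its neighbours — this is what makes
node masking a meaningful self-supervision signal. Isolated spots have
all-zero rows in `Â` and embed to zero.

For multi-slice work, aligned slices are stacked with slice *s* at
`z = s · z_gap`, where `z_gap` defaults to the median within-slice
nearest-neighbour distance ("one spot pitch"), and a single KNN graph is
built in 3-D so edges can cross slices.

## Dual masking

Each training epoch draws fresh masks (re-sampling per epoch is the
standard masked-autoencoder schedule; fixing masks once was considered and
not used):

* node mask: a uniform random subset of exactly `floor(ρ_m · N)` spots
  (default `ρ_m = 0.3`); their feature rows are replaced by a learnable
  token initialised at zero,
* edge mask: each undirected edge dropped independently with probability
  `ρ_d` (default 0.4; 0.5 is sensible for high-resolution FISH-type data).
  The Bernoulli draw applies to the undirected pair, so the masked
  adjacency stays symmetric.

## Network and losses

Encoder `H = Â·PReLU(BN(Â X W_g0))·W_g1` with widths 512 → 256; decoder
`Z = Â·PReLU(BN(H̃ W_d0))·W_d1` (linear then GCN; hidden width 256, a
choice — only "a linear layer followed by a GCN layer" is prescribed).
Before decoding, latent rows of masked spots are replaced by a second
learnable token (re-masking). Batch norm uses batch statistics during
optimisation and running averages (momentum 0.1, eps 1e-5) at inference;
PReLU has one learnable slope per layer, initialised at 0.25; graph layers
are biasless, so zero input propagates to zero output.

The reconstruction loss is the scaled cosine error over masked spots with
`γ = 2` (norms guarded by ε = 1e-8). The contrastive channel feeds the
*unmasked* features with the *masked* graph through the same encoder
object; the dropped edges are the positives, and for every node with `n_i`
incident positives, `n_i` negative partners are drawn uniformly without
replacement from its non-neighbours (nodes adjacent to everything are
skipped with a warning). The discriminator is a two-layer MLP on the
Hadamard product of the pair's embeddings — hidden width 256, sigmoid
output; the Hadamard composition makes it symmetric in its arguments. The
printed form of this discriminator in the source literature has unbalanced
parentheses; the standard two-layer reading
`σ(w₂·ReLU(W₁(h_i⊙h_j)+b₁)+b₂)` is implemented. The NCE loss clamps log
arguments at 1e-12. The combined objective is
`(1 − λ)·L_SCE + λ·L_NCE`, `λ = 0.7`.

Optimisation is Adam (lr 1e-3, β = (0.9, 0.999), eps 1e-8) with L2 weight
decay 2e-4 added to the gradient of every parameter that the active
channels touch; parameter groups whose loss weight is zero in a given
configuration (e.g. the decoder at `λ = 1`) are excluded from the step
entirely so they remain bit-identical to their initialisation. The default
epoch budget is 1000 with no early stopping (an epoch count is a
per-dataset choice; small graphs converge much earlier, and the end-to-end
tests in this repository use 300 — or 150 for the repeated ablation runs —
which loss traces show is well past convergence at the 900-spot scale).

The whole network is implemented in numpy (float32 forward/backward,
float64 loss reductions) with hand-written gradients; every gradient path
is checked against central finite differences in the test suite. Training
is single-threaded-deterministic: one `numpy` generator seeds mask draws
and negative sampling, and parameter initialisation is Xavier-uniform from
a separate seeded generator.

## Inference, clustering, denoising

Inference is always unmasked: the shared encoder on `(X, Â)` with BN in
running-average mode. (Which channel's view to use at read-out is not
prescribed anywhere; the shared encoder on the full data is the natural
common read-out.) Clustering takes the top 30 PCs of the embedding and
runs k-means (k-means++, 10 restarts, 300 iterations, fixed seed); the
number of domains is user-supplied. Denoising trains the same
architecture on the scaled HVG matrix without PCA and returns
`decode(encode(X, Â), Â)` with no masking.

## Ablation variants

The trainer exposes the ablation wirings as presets: single-channel
combined (`one_channel_combine`: masked features *and* masked graph through
one pass used by both losses), dual-channel with either or both masks
removed, each channel alone with and without its mask, positives taken from
the *remaining* edges (`pos_sel_remain`), and uniformly random negatives
(`neg_sel_random`, matched in count to the default scheme's `2·|E_pos|`).
When a variant disables node masking the reconstruction targets all spots;
when it disables edge masking the positive set is the whole edge set —
the unmasked channels degenerate to a plain graph autoencoder /
all-edge contrastive learner rather than to an error path, which is what
makes the no-masking baselines trainable and comparable.

## Multi-slice alignment

Vertical (serial-section) alignment is rigid point-to-point ICP:
nearest-neighbour correspondences, least-squares rotation + translation by
SVD of the cross-covariance, iterated to `tol = 1e-6` or 50 iterations.
Because plain ICP only converges locally, the iteration restarts from a
small fixed set of initialisations (identity and principal-axes
alignments, each centroid-pre-aligned) and keeps the solution with the
lowest final mean correspondence distance; this makes pure translations
exact in one step and recovers rotations of at least ±30° on
non-degenerate slices. Collinear or coincident reference points trigger a
rank warning and a translation-only fit. Scaling/affine/non-rigid warps
are out of scope.

Horizontal alignment translates the second slice by
`Δx = max(x₁) − min(x₂)` and `Δy = ȳ₁ − ȳ₂`, where `ȳ` is the mean y of the
slice's edge band — the spots within the top (respectively bottom) 1% of
the x range, a quantile-band reading of "the edge points" that is robust to
jitter; the band width is configurable.

## Metrics

ARI is the standard permutation-adjusted Rand index; ACC is best-matched
accuracy via Hungarian assignment on the contingency table (optimal, not
greedy). DIS — the discreteness of a labelling — is the mean over spots of
the fraction of spatial-graph neighbours with a different label (isolated
spots contribute 0); it is 0 for perfectly coherent domains and bounded by
1. Moran's I and Geary's C use the binary spatial adjacency as weights.
F1LISI combines the local inverse Simpson's index of batch labels (iLISI,
mixing) and of domain labels (cLISI, purity): per-spot label distributions
are perplexity-calibrated Gaussian kernels over embedding neighbours
(perplexity 30, 3×perplexity neighbours, t-SNE-style bandwidth search),
medians across spots are normalised to [0, 1] by the label counts, and the
harmonic mean of iLISI_n and (1 − cLISI_n) is clipped to [0, 1]. DIS and
the F1LISI composition follow the properties and limits their originating
descriptions state (range, ideal-mixing → 1, no-mixing → 0); the exact
published formulas for these two scores are not in the public text, so the
implementations here are documented conventions validated by those limits.

## Synthetic data

The generator plants what the model is designed to exploit and nothing
else: spots on an integer grid; spatially contiguous domains (horizontal
bands, or Voronoi blobs around random centres); per-domain marker blocks
whose log-mean is raised by `effect_size` inside their domain; counts drawn
negative-binomially (gamma–Poisson, `var = μ + α μ²`, default `α = 0.3`, a
typical sequencing-data overdispersion) around `exp(log-mean)` with
per-gene baselines `Normal(0.7, 0.2)` on the log scale (~2 counts per gene
before dropout); independent multiplicative dropout (default 0.6)
emulating the sparsity of spot-level data; and, for multi-slice data,
per-slice gene-wise log-shifts `Normal(0, batch_shift_sd)` as a batch
effect plus optional rigid misalignment of later slices. The default
"smoke" slice is a 30×30 grid with 4 band domains, 200 genes, 10 markers
per domain, effect 1.0, dropout 0.6, seed 0; the integration scenario uses
two such slices with `batch_shift_sd = 0.8`.

Not emulated: platform-specific artefacts (Visium spot mixing, FISH
segmentation error), spatial gradients within domains, cell-type mixtures
within spots, gene–gene correlation beyond the domain programs, and
mean–variance trends beyond the single NB dispersion. Passing the
end-to-end tests therefore demonstrates that the implementation recovers
planted, contiguous, marker-driven structure under heavy sparsity and
batch shifts — not that it matches any particular published benchmark
number on real tissue.

## Numerical and degenerate-input choices

Cosine similarities are clipped to [−1, 1]; zero-norm rows are guarded by
ε = 1e-8; NCE log arguments clamped at 1e-12; zero-variance genes scale to
zeros; zero-degree graph rows stay zero through normalisation and the
encoder; `k ≥ N` is clipped to `N − 1` with a warning; empty masked-node or
positive-edge sets raise in the loss functions themselves (the variant
presets, not the losses, decide fallback target sets); duplicate
coordinates are allowed (distance-0 edges permitted). All stochastic
components accept either a seed or a shared `numpy.random.Generator`.

## Known limitations

Counts are kept dense in memory, sized for panels up to a few thousand
genes and tens of thousands of spots rather than whole-transcriptome
atlases. The estimators are transductive (the fitted graph defines the
embeddable spots). Cluster-number selection, histology features, spot
deconvolution and non-rigid registration are out of scope.
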