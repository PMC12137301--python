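# Methods

## Problem and model

stGuide transfers categorical annotations (tissue domains, cortical
layers, tumor regions) from annotated *reference* spatial
transcriptomics sections to unannotated *query* sections. Each section
("slice") provides a spots × genes count matrix and 2-D spot
coordinates; reference slices additionally carry a per-spot label from
a shared vocabulary of `K_a` categories. Slices differ by batch
effects, and the reference annotation may be strongly imbalanced.

The method embeds all spots into a shared `d`-dimensional space with a
graph attention autoencoder and trains in two phases.

**Composed graph.** Within each slice, every spot is joined to its
`avg_k = 5` nearest spatial neighbors (Euclidean distance in platform
coordinates, symmetrized union, so 5 is the minimum and approximate
average degree). Across every pair of slices, spot pairs that are
mutual `k = 5`-nearest neighbors in expression feature space are
joined; requiring mutuality suppresses spurious matches between
batch-shifted slices. The feature space for the MNN search is the top
50 principal components of the per-gene standardized (clipped at ±10
SD) log-normalized expression — the standard single-cell workflow;
k-NN directly in the several-thousand-dimensional HVG space is noisy.
Distance ties break toward the lower spot index, making edge sets
deterministic. `G1` spans the reference slices only; `G2` spans
reference plus query slices and is built independently of `G1` (its
PCA and MNN search see the query data).

**Encoder.** Two stacked graph attention (GAT) layers with dimensions
`[m, 512, 10]` and `Q = 3` heads. For head `q`, the attention logit
between node `i` and neighbor `j` is
`LeakyReLU(a_q^T [W_q h_i ‖ W_q h_j])` (negative slope 0.2),
softmax-normalized over the neighborhood of `i` *including* `i` (the
self-loop is added inside the layer and never stored in the graph).
Head outputs are averaged (the `1/Q` aggregation), passed through ELU;
the final layer is linear so the latent space is unconstrained.

**Decoders and classifier.** Each slice owns a linear + BatchNorm
expression decoder `x' = γ_i (W z + b − μ_i)/√(σ²_i + ε) + β_i`
(ε = 1e-5; training mode uses slice-batch statistics with running
averages tracked at momentum 0.1, evaluation mode the running
statistics); slice-specific normalization lets one shared latent space
reconstruct batch-shifted profiles. The adjacency decoder is the inner
product `sigmoid(z_i · z_j)`. Phase 1 adds a linear softmax classifier
over the latent space.

**Objectives.**

- expression: mean over spots of the squared Euclidean reconstruction
  error;
- adjacency: binary cross-entropy between the composed-graph adjacency
  and its reconstruction, averaged over all `n²` entries (probabilities
  clamped to `[1e-7, 1−1e-7]`). On graphs above 2,000 nodes the dense
  `n²` block is replaced by
  all positive entries plus an equal-size uniform sample of negatives;
- classification (phase 1): mean categorical cross-entropy over
  reference spots;
- alignment (phase 2): mean per-spot squared distance between the
  joint reference embedding `z_r'` and the frozen phase-1 embedding
  `z_r` — gradients flow only into `z_r'`;
- totals: `L_A + α L_G + β L_c` (phase 1) and `L_A + η L_G + θ L_TL`
  (phase 2) with `α = β = η = θ = 10`.

**Label transfer.** Each query spot receives the label of its most
cosine-similar reference spot in the joint embedding (`k = 1`); a
top-`k` majority vote (ties → higher summed similarity → lower label
code) is available. Evaluation reports accuracy (literal code
equality — valid because predictions live in the reference
vocabulary), pair-counting adjusted Rand index, and
`2I/(H+H')`-normalized mutual information, both computed from the
contingency table; degenerate single-cluster cases return 1 by the
usual convention.

## Optimization

Training differentiates through a small purpose-built reverse-mode
engine on numpy arrays (`stguide._autograd`), with gradients verified
against central finite differences in the test suite. Attention is
materialized densely per head; the package targets desk-scale graphs
(≲ 2,000 nodes), beyond which memory grows quadratically — a known
limitation.

Both phases use full-graph Adam steps. Defaults: learning rate 2e-3,
weight decay 1e-4, 800 epochs per phase, Glorot-uniform initialization
from a seeded generator. The learning rate is higher than the 1e-3
habitual for graph autoencoders because the expression term (a squared
norm over all genes) dominates the total by two to three orders of
magnitude while BatchNorm makes it nearly scale-invariant in `z`: at
1e-3 the classifier term is still near its chance plateau (`log K_a`)
after 1,000 epochs and latent norms collapse toward zero. At 2e-3 the
supervised term converges in a few hundred epochs; 5e-3 was unstable on
long runs. The phase-2 encoder is freshly initialized (seed offset +1)
rather than warm-started — alignment to `z_r` is driven by the transfer
penalty, not parameter sharing; a warm-start flag exists. No early
stopping by default, to keep runs exactly reproducible.

The phase-1 target `z_r` is the final-epoch embedding computed after
training (the encoder has no stochastic layers, so train/eval forward
passes coincide; BatchNorm affects only the decoders).

## Synthetic data

The generator emulates multi-slice data over layered tissue, the
geometry of the cortical-layer benchmarks this class of method is
evaluated on: classes are horizontal bands on a regular grid, so
spatial neighborhoods are label-coherent away from band boundaries.
Per gene, a baseline natural-log mean is drawn once (Normal(1.0, 0.5))
and shared by all slices; each layer owns a disjoint set of marker
genes elevated by `marker_effect` (log scale) inside the layer; each
slice draws an i.i.d. per-gene log shift of SD `batch_effect_sd`
(batch effect); counts are negative-binomial with dispersion 0.3
(variance `μ + 0.3μ²`), or optionally Gaussian reals. Spots whose
sampled row is entirely zero (essentially impossible at the defaults)
receive a single guard count so library-size normalization is defined.

Frozen presets:

| preset | slices (ref+query) | grid | layers | genes (markers/layer) | marker | batch SD |
|---|---|---|---|---|---|---|
| tiny | 1+1 | 8×8 | 4 | 50 (4) | 2.0 | 0.2 |
| easy | 2+1 | 64×4 | 4 | 100 (10) | 2.0 | 0.2 |
| null | 2+1 | 64×4 | 4 | 100 (10) | 0.0 | 0.2 |
| imbalanced | 2+1 | 20×8 | 4 (5/30/30/35%) | 100 (10) | 2.0 | 0.2 |
| balanced | 2+1 | 20×8 | 4 | 100 (10) | 2.0 | 0.2 |
| strong_batch | 2+1 | 8×8 | 4 | 100 (10) | 2.0 | 2.5 |

`marker_effect = 2.0` (≈ 7.4-fold) with 10 markers per layer over 100
genes makes the easy preset trivially separable — a nearest-centroid
classifier on log-normalized expression reaches accuracy 1.00 — so an
end-to-end failure there indicts the pipeline, not the data. The 64-row
grid gives 16-row-thick bands: as in real laminar tissue, interior
spots dominate and spatial smoothing helps rather than blurs. (On thin
2-row bands every spot borders another class and attention averaging
caps attainable accuracy — worth knowing when applying the method to
finely interdigitated tissue.) The imbalanced preset allocates one of
twenty grid rows (5% of spots) to the rarest layer.

What the generator does *not* emulate: spatially varying library size,
spot-swapping and segmentation artifacts, curved or branching domain
geometry, gene-gene correlation beyond the shared programs, and
platform-specific count distributions. Passing tests therefore show
the machinery recovers a planted signal under batch shifts and
imbalance — not that performance transfers to any particular real
dataset.

## Numerical choices

- Library-size target 10,000 counts/spot, then `log1p`; zero-total
  spots are an error naming the offending rows.
- HVGs: per-slice mean-binned normalized dispersion (Seurat flavor) on
  log-normalized data, top 5,000 (clipped to the gene count), ranking
  ties broken lexicographically; the cross-slice intersection is sorted
  lexicographically.
- Attention masking uses an additive −1e30, which underflows to an
  exact zero after `exp`, so attention rows sum to 1 to machine
  precision.
- Probability clamps at 1e-7 for every logarithm.
- All RNG flows through seeded `numpy` generators: simulation from
  `SimConfig.seed`, phase-1/phase-2 initialization from
  `TrainConfig.seed` and `seed + 1`. Single-threaded runs are bitwise
  reproducible.

## Known limitations

- Dense attention and dense adjacency reconstruction bound practical
  graph size to a few thousand spots; the sampled adjacency loss
  extends training but not the attention memory footprint.
- The alignment penalty is a plain L2 match of embeddings; nothing
  constrains query spots of a class absent from the reference, which
  will be assigned the nearest present class (the cosine similarity
  diagnostic is exported so users can threshold).
- Accuracy is literal code equality by design; it is meaningful only
  for transferred labels, not for de-novo clusterings.
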