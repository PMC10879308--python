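# Methods

This note documents the model implemented in `repomet`, the numerical
and design choices that were genuinely open, what the synthetic
benchmark does and does not show, and the package's known limitations.

## Model

### Heterogeneous network

Inputs are a binary association matrix `Y ∈ {0,1}^{M×N}` and two
similarity matrices `S_r` (drugs), `S_d` (diseases), values in [0, 1],
unit diagonal. Each similarity matrix is symmetrically degree-normalized,
`S' = E^{-1/2} S E^{-1/2}` with `E = diag(Σ_j S_ij)`, scaled by the
penalty factor μ, and placed on the diagonal blocks of the joint
adjacency `G`; `Y` and `Yᵀ` fill the off-diagonal blocks. μ (default 6)
balances how strongly the similarity channels contribute relative to the
association channel. The graph convolution renormalizes `G` by its own
degree a second time; the two normalizations are deliberate and kept
distinct (the first acts within a similarity network, the second across
the joint graph). Nodes isolated in `G` receive a unit self-loop before
degree inversion, which would otherwise be undefined.

### Completion stage

The encoder input `H⁰ = G·W_in` is a linear projection of each node's
adjacency profile — the only node features the problem supplies — into
the embedding dimension k. L graph-convolution layers with ReLU follow,
and a trainable attention vector `β` (initialized to `β_l = 1/(l+1)`,
l = 0..L, the input projection included) combines the per-layer
embeddings. A bilinear decoder with sigmoid produces pair scores in
(0, 1). The loss is binary cross-entropy over *all* M·N pairs, with each
positive weighted by `η = |Y⁻|/|Y⁺|` so that the two classes contribute
comparably despite the extreme sparsity; sigmoid outputs are clamped to
[1e-7, 1−1e-7] inside the logs.

Optimization is full-batch Adam (lr 0.008). Regularization follows the
stated discard rates: rows of the input features are dropped at rate 0.6
(node dropout) and each layer's embedding is dropped elementwise at rate
0.4 where it enters the attention combine. Gradients are hand-derived
reverse-mode expressions verified against central finite differences to
~1e-7 relative error; the graphs involved (hundreds of nodes) make dense
numpy the simplest correct implementation, and every stochastic choice
flows from one explicit generator, so runs are bit-reproducible.

Training stops at a relative loss-improvement below `tol` (1e-5) held for
10 consecutive epochs, or at the epoch cap (600). Because dropout makes
single-epoch score snapshots noisy, the returned score matrix is the
mean of the evaluation-mode (dropout-free) scores over the trailing 50
epochs; this substantially stabilizes which zero entries pass the
screening threshold between otherwise identical runs.

Screening: entries with score ≥ θ keep their *score* (a soft positive);
known positives are pinned at 1; everything else returns to 0. The
alternative reading — keeping the original binary entry — would make the
step a no-op for zero entries, so the score-keeping reading is used.
θ defaults to 0.8 ("highly confident"); it is exposed in the
configuration, as are switches for freezing the attention weights and
excluding the input projection from the attention sum.

### Metric stage

Latent vectors α_r, β_d (n = 250) are initialized from Normal(0.1,
variance 0.03) — the spread is read as a *variance* (std ≈ 0.173), with a
config switch for the std reading — and margins uniformly in (0, l],
l = 1. Positives are all entries of the completed matrix strictly greater
than zero, unweighted. Per epoch, the positives are shuffled into
batches of 512; each positive receives P = min(M, N) negatives drawn
uniformly without replacement from the anchor's zero-entry partners,
independently for the drug-centric and disease-centric hinge. Gradients
of the hinge sums and of the adaptive-margin reward are applied with
AdaGrad (lr 0.05), after which vectors are projected onto the l-ball and
margins clamped to [1e-6, l].

**Convergence check.** 5% of positives are held out as a validation set.
The monitored quantity is the validation *ranking AUC* (validation
positives against all zero pairs, by negated distance), not the
validation triplet loss: the adaptive-margin term grows every margin
during training, which mechanically inflates every validation hinge term
even while the ranking itself is still improving, so validation loss
rises from early epochs and would stop training far too soon (observed:
AUC 0.69 at the loss-based stop vs 0.74 at the ranking plateau).
Training stops when validation AUC has not improved for 15 epochs and
the best-validation parameters are restored. With `val_fraction = 0` the
check is disabled and the final-epoch model is returned.

### Prediction and cold start

The prediction matrix is the pairwise squared distance; candidates are
ranked ascending with ties broken lexicographically by partner
identifier (reproducibility). A new entity is embedded as the
similarity-weighted mean of its h = 5 most similar training entities'
vectors (unweighted mean available via a flag), then clipped onto the
l-ball. Re-embedding does not retrain the model.

## Evaluation protocols

Cross-validation partitions *known positives* (repeats × folds); all
pairs that are not training positives form the candidate set. AUC and
AUPR are computed globally over that set (a per-drug averaged mode of the
same quantities is available through the per-drug K-metrics); p@K and
r@K are computed per drug and averaged over drugs with at least one test
positive, matching the recommendation framing. AUC is the tie-aware
rank-sum statistic; AUPR is step-wise precision–recall summation
(equal to average precision), cross-checked against scikit-learn in the
tests. The leave-one-entity-out protocols zero one drug's (disease's)
row, retrain, cold-start re-embed the entity, and score only its
partners; the independent protocol trains on the full matrix and tests
on a second matrix over the same entities, excluding training positives
from the candidates.

## Synthetic worlds

The generator plants M drug and N disease latent positions around shared
Gaussian cluster centres (5 centres, spread 0.4). True affinity is
`exp(-d²)` of latent distance; the observed positives are the top
`density·M·N` affinity pairs, after which a `noise` fraction of positives
is swapped with random zero pairs. Within-type similarities are
`exp(-d²/2)` kernels with unit diagonal. The defaults — M = 60, N = 80,
latent dimension 8, density 0.05, noise 0.05 — keep every end-to-end
test inside a few minutes on one CPU while leaving the planted signal
clearly above chance.

What this emulates: the coupling "similar drugs treat similar diseases",
extreme sparsity, and label noise. What it does not: the skewed degree
distributions, block sizes and annotation biases of curated benchmark
datasets, or any real chemistry/semantics behind the similarity values.
Passing the recovery tests shows the implementation can extract planted
low-dimensional structure at realistic sparsity; it is not evidence
about performance on any particular real dataset.

## Problem sizes and training lengths in the shipped tests

Unit tests run reduced configurations (k = 8–16, 2 layers, latent
dimension 4–32, tens of epochs). The end-to-end recovery computation
uses the default world with 20% of positives held out, completion at its
defaults, and metric training capped at 60 epochs — past the plateau at
which the held-out ranking stops changing on this problem size. The
recovery is measured for the full pipeline and for a metric-only
ablation across five run seeds; completion improves held-out AUPR in the
majority of seeds and raises AUC on the order of +0.10, consistent with
the completion stage supplying the similarity information that pure
collaborative metric learning lacks. Run-to-run variability of held-out
AUC is a few hundredths on this problem size, driven by negative
sampling and dropout; single-seed values should be read with that in
mind. The cold-start comparison uses a 60 × 240 world because with only
80 candidate diseases a random ranking already recovers ~62% of
positives in any top-50 list, leaving recall@50 non-discriminative.

## Known limitations

- Dense O((M+N)²) linear algebra throughout: intended for desk-scale
  matrices (up to a few thousand entities), not genome-scale graphs.
- The disease similarity matrix is consumed as given; no semantic
  similarity computation is provided. Jaccard similarity over binary
  feature profiles is available for drugs (or any entity type).
- Margins enter training but not prediction; distances are not
  calibrated into probabilities.
- The completion threshold θ interacts with the class balance of stage
  2; very low θ floods the positive set with soft positives. The default
  0.8 admits roughly as many soft positives as there are known positives
  on the default world.
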