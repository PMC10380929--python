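# Methods

## Model

The classifier maps a per-sample gene-expression vector `g ∈ [0,1]^n` to a
case probability through two parallel branches.

**Pathway branch.** `p = tanh(((W_p ∘ M) g) ⊙ u)`. `M` is the m×n binary
pathway-membership matrix built from a GMT collection filtered to pathways
with at least `min_genes` (default 10) members inside the expression gene
universe. The mask is applied by element-wise multiplication *inside every
forward pass*, not by one-time zeroing, so masked positions of the effective
weight `W_p ∘ M` are exactly zero at all times and receive identically zero
gradient under any optimizer. The branch has no bias term. `u` is the
per-pathway normalization vector: `1`, `1/n_i`, or `1/√n_i` of the pathway
size `n_i` (row sum of `M`), default `1/√n_i`. Under Xavier initialization
the `1/√n_i` choice makes the pre-activation variance of a pathway node
independent of its size, which is what keeps attributed importance from
correlating with set size (see the ablation below).

**Fully connected branch.** `f = tanh(W_f g + b_f)` with `n_fc` nodes
(grid candidates 32/64/128).

**Head.** `[LayerNorm(p); LayerNorm(f)]` → dropout(0.3) → 64-unit tanh
hidden layer → dropout(0.3) → 2-logit softmax. The reported model output
`o` is the case-class probability. Layer-norm uses learned affine parameters
and epsilon 1e-5. Dropout is placed on the concatenated pathway-layer output
and on the hidden-layer output; the model in evaluation mode is
deterministic. All weights are Xavier-uniform initialized from the
configuration seed; biases, layer-norm shifts start at zero, gains at one.

The unmasked baseline (`BaselineDNN`) replaces the two branches by a single
fully connected first layer (candidates 128/512/1024/4096 nodes), keeping
the same activations, layer normalization, dropout and head.

## Training protocol

Stratified 10-fold cross-validation: fold k's test set is the k-th
stratified partition; one stratified ninth of the remainder is the
validation set (8:1:1 overall). Per fold and hyperparameter grid point, the
training split — and only the training split — is SMOTE-oversampled to exact
class balance (k = 5 nearest minority neighbors, Euclidean; each synthetic
point is `α·x_i + (1−α)·x_j`, `α ~ U[0,1]`). Optimization: Adam
(β = 0.9/0.999), cross-entropy, mini-batch 64, reduce-on-plateau on the
validation AUC (factor 0.5, patience 5, floor 1e-6), early stopping after 10
epochs without validation-AUC improvement, best-epoch weights restored,
epoch cap 200 by default. The grid point with the best validation AUC is
selected per fold; test AUC (case-class probability) and F1 (case class,
threshold 0.5) are computed once on the untouched test split. Training is a
pure function of (data, seed): stage seeds are derived from the global seed
by hashing, and two runs produce bit-identical reports.

## Attribution

Contributions are computed with the multi-reference DeepLIFT rescale
estimator (the Deep SHAP scheme). The reference set is a class-balanced
random subsample of the fold's training samples (default 100, seeded); the
reference output `ȳ` is the model's mean case probability over it. For each
(evaluation sample, reference) pair, multipliers are propagated from the
case-class output to the chosen input layer and contributions
`m_i (x_i − x̄_i)` are averaged over references.

Propagation rules, each exactly satisfying summation-to-delta:

- linear maps: transposed weights;
- tanh and the softmax head (rewritten as a sigmoid of the logit
  difference): slope `Δout/Δin`, with the analytic derivative where
  `|Δin| < 1e-7` (the induced completeness error is O(Δin²), far below
  the 1e-3 tolerance used in tests);
- layer normalization: an exact decomposition. With `z = a − mean(a)` and
  `s = √(mean(z²)+ε)`, the difference of `1/s` between sample and reference
  is itself a linear functional of `Δz`
  (`1/s_x − 1/s_r = −mean((z_x+z_r)⊙Δz)/(s_x s_r (s_x+s_r))`), so the whole
  block is linear in `Δz` with endpoint-dependent coefficients. No
  frozen-statistics approximation is needed, and completeness holds to
  machine precision (observed ≲ 1e-15).

Gene-level attribution propagates to the input layer. Pathway-node
attribution treats the pre-normalization branch activations `(p, f)` as the
input layer of the downstream sub-network; completeness then holds over the
full concatenated layer, and the pathway rows are reported. One consequence
of the exact treatment worth knowing: a node severed from the hidden layer
(all outgoing weights zero) can retain a small residual attribution, because
the output still depends on it through its branch's layer-norm statistics.
This is genuine sensitivity, not leakage; the residual vanishes only when
the whole branch is severed.

**Importance score.** Per fold: `s_i` = mean |contribution| of node *i* over
the fold's test samples, z-scored across nodes (population SD); the
importance score is the mean z-score over the ten folds.

**Known-gene test.** Two-sample rank-sum (Mann-Whitney) comparison of
importance scores, known genes vs the rest; exact null enumeration below 25
total observations without ties, otherwise the tie-corrected normal
approximation. One-sided ("known > rest") and two-sided p-values are
reported.

**Feature selection.** Samples split into ten stratified parts; per repeat,
eight parts train the masked model, one part ranks genes by single-model
mean |contribution|, and a fresh MLP with layer widths {n, n/2, n/4, 2}
(tanh, dropout 0.3, same SMOTE/early-stopping policy) is trained on the top
10% of genes (boundary ties kept) and scored on the held-out part, against a
size-matched random gene set and the all-genes arm.

## Synthetic benchmark

The generator emulates the data shape the model expects. Baseline expression
is Gaussian noise (sd 1.0), optionally equicorrelated across genes within a
sample (default correlation 0 — independent backgrounds). Pathways are
sampled with sizes uniform on [10, 60] and members drawn freely, so sets
overlap as in real ontologies. Disease signal: 5 designated signal pathways
each contribute 4 distinct member genes (20 truth genes) whose case-group
mean is shifted by 1.5 pre-scaling units. Labels use a fixed case count
`round(0.33 · n_samples)` (1:2 imbalance, exercising SMOTE); each gene is
then min-max scaled to [0, 1] (clipped against floating-point round-off).
The default benchmark is 300 samples × 1000 genes × 50 pathways. All outputs
are pure functions of (config, seed).

What the generator does *not* emulate: probe-level microarray structure,
batch effects, heavy-tailed or count-valued expression, co-expression
modules beyond optional equicorrelation, and label noise. Passing tests on
this benchmark therefore demonstrate the correctness of the machinery
(masking, training protocol, attribution, ranking) and its behavior under a
clean planted signal — not the classification performance to expect on real
cohorts.

A structural property of the benchmark worth flagging: truth genes are
necessarily pathway members, and pathway members — especially genes in many
pathways — receive systematically larger attribution mass from the masked
branch even when no signal is planted (at zero effect size, gene importance
correlates ≈ 0.7 with membership count). A rank-sum test of "truth genes vs
all background" under the null therefore rejects far more often than the
nominal rate for the masked model, while the unmasked baseline shows no such
bias. This is a property of the pathway prior itself, not of the attribution
estimator.

## Problem sizes and budgets

The package's benchmark protocol uses a single hyperparameter point
(n_fc = 64, learning rate 1e-3; baseline width 128) and an epoch cap of
40-100 depending on the experiment; early stopping almost always fires well
below the cap, and the paper-scale 3×3 grid remains the library default
(`train.DEFAULT_GRID`) for users who want the full search. The
normalization-mode ablation uses 20 replicates of a 200 × 400 × 40-pathway
configuration; multi-seed studies use ten seeds of the default benchmark.

## Numerical choices

- IQR uses linear interpolation between order statistics (the numpy/pandas
  default); IQR ties in probe filtering and probe→gene collapse keep the
  first occurrence in input order.
- Min-max scaling maps constant genes to 0; fitting on the full dataset is
  the default (matching dataset-level preprocessing), with a train-only
  option (optionally clipped) to avoid leakage in new analyses.
- Per-fold importance z-scores use the population standard deviation; a fold
  whose mean absolute attributions are constant across nodes is an error.
- Non-finite training loss aborts the grid point and continues the search.
- Seed derivation: SHA-256 of (seed, stage tokens), truncated to 31 bits.

## Known limitations

- The exact layer-norm attribution is specific to this architecture; adding
  layers requires writing their propagation rule.
- Dropout placement (both the concatenated layer and the hidden layer) is a
  documented choice; the pathway branch carries no bias, all other layers do.
- The rank-sum known-gene comparison inherits the membership bias described
  above whenever the known set is drawn from pathway members; comparisons
  restricted to pathway-covered genes are less affected but not unbiased.
- SMOTE operates in the scaled [0,1] gene space with Euclidean distances; at
  very high gene counts distance concentration makes the neighbor choice
  nearly arbitrary, as for any SMOTE application to transcriptomes.
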