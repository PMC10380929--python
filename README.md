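# pinnet

A pathway-prior-informed neural network for case/control classification from
gene-expression matrices, with attribution-based interpretability.

## The problem

Deep classifiers separate disease from control transcriptomes well, but a
dense network says nothing about *which* genes or biological processes drive
its predictions. `pinnet` addresses this by building curated gene sets (GO /
KEGG collections in MSigDB GMT format) directly into the architecture and by
recovering per-gene and per-pathway contribution scores from the trained
model. It is aimed at researchers who want both a classifier and a ranked,
biologically structured list of candidate markers from a samples × genes
expression matrix.

## The model

Each expression profile `g ∈ [0,1]^n` feeds two parallel branches:

- **pathway branch** — `p = tanh(((W_p ∘ M) g) ⊙ u)`, where `M ∈ {0,1}^{m×n}`
  is the binary pathway-membership matrix (`M_ij = 1` iff gene *j* belongs to
  pathway *i*). The element-wise mask is applied inside every forward pass,
  so pathway node *i* receives input only from its member genes, and masked
  weights have identically zero gradients. `u_i ∈ {1, 1/n_i, 1/√n_i}`
  rescales each node by its pathway size `n_i` (default `1/√n_i`) so that
  node magnitude — and hence attributed importance — does not grow with set
  size.
- **fully connected branch** — `f = tanh(W_f g + b_f)`, capturing signal
  outside the annotated sets.

Both branches are layer-normalized, concatenated
(`[LayerNorm(p); LayerNorm(f)]`), and passed through dropout (0.3), a 64-unit
tanh hidden layer, and a 2-logit softmax head. Training uses cross-entropy,
Adam with mini-batches of 64, a reduce-on-plateau learning-rate schedule, and
early stopping on validation AUC, inside stratified 10-fold cross-validation
with an 8:1:1 train/validation/test split; the training portion of each fold
is SMOTE-oversampled to exact class balance.

Interpretation uses a multi-reference DeepLIFT-rescale estimator (the Deep
SHAP scheme) against a class-balanced reference set: contributions satisfy
summation-to-delta, `Σ_i C_i = y − ȳ`, to floating-point precision — the
layer-norm step is handled with an exact difference-linear decomposition
rather than an approximation. Per fold, nodes are scored by mean absolute
contribution over the fold's test samples and z-scored across nodes; the
**importance score** of a gene or pathway node is its mean z-score over the
ten folds.

Everything runs on plain numpy; no GPU or deep-learning framework is needed.

## Worked example

The package ships a synthetic-data generator that emulates the expected data
shape: a MinMax-scaled expression matrix, imbalanced binary labels, an
overlapping pathway collection, and 20 "disease genes" planted inside 5
designated pathways.

```python
from pinnet import (default_benchmark, build_mask, filter_pathways,
                    cross_validated_importance, known_gene_test, TrainOptions)

dataset, pathways, truth, cfg = default_benchmark(seed=1)      # 300 x 1000
collection = filter_pathways(pathways, dataset.gene_ids, min_genes=10)
mask = build_mask(collection, dataset.gene_ids)                # 50 x 1000

table, cv = cross_validated_importance(
    dataset, mask, grid=((64, 1e-3),), opts=TrainOptions(max_epochs=100), seed=1)
print(f"mean test AUC {cv.mean_test_auc:.3f}, mean F1 {cv.mean_test_f1:.3f}")
res = known_gene_test(table, truth.signal_gene_ids)
print(f"planted genes vs background: one-sided rank-sum p = {res.p_one_sided:.2e}")
```

Output:

```
mean test AUC 0.982, mean F1 0.846
planted genes vs background: one-sided rank-sum p = 9.24e-15
```

The AUC says the network separates cases from controls almost perfectly on
this benchmark (a logistic-regression oracle on the 20 truth genes alone
certifies ≥ 0.85 is attainable); the rank-sum p-value says the 20 planted
genes sit far above the 980 background genes in the cross-validated
importance ranking — the interpretability pipeline recovers the planted
signal.

The same pipeline is scriptable from the shell:

```bash
pinnet simulate --seed 1 --out sim/
pinnet train --expr sim/expr.tsv --labels sim/labels.tsv --gmt sim/sets.gmt --out run/
pinnet interpret --expr sim/expr.tsv --labels sim/labels.tsv --gmt sim/sets.gmt \
    --known <(python -c "import json;print('\n'.join(json.load(open('sim/truth.json'))['signal_gene_ids']))") \
    --out importance.tsv
```

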