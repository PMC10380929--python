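"""Attribution and importance analysis.

Gene and pathway-node contributions are computed with the multi-reference
DeepLIFT rescale estimator (the Deep SHAP scheme): for every evaluation
sample x and reference sample x_bar, multipliers are propagated from the
case-class output back to the chosen input layer, and contributions
``C_i = m_i * (x_i - x_bar_i)`` are averaged over references.  Each
propagation rule satisfies summation-to-delta locally, so contributions sum
to ``y - y_bar`` to floating-point precision:

* linear maps use the transposed weights (exact);
* elementwise tanh and the 2-logit softmax (rewritten as a sigmoid of the
  logit difference) use the rescale rule delta-out / delta-in, falling back
  to the analytic derivative when delta-in is tiny;
* layer normalization uses an exact decomposition: the delta of 1/sigma
  between sample and reference is itself a linear functional of the centered
  deltas, so the whole block is linear in delta with endpoint-dependent
  coefficients -- no frozen-statistics approximation is needed.

Cross-fold importance scores follow the absolute-mean-then-z-score recipe:
per fold, score each node by the mean absolute contribution over that fold's
test samples, z-score across nodes, and average the z-scores over folds.
Downstream analyses: rank-sum comparison of known versus background genes,
pathway-size versus importance correlation, and the top-fraction
feature-selection experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from ._utils import derive_seed
from .model import LN_EPS, BaselineDNN, MLP, PINNet, PINNetConfig
from .pathways import MaskMatrix
from .preprocess import ExpressionDataset
from .train import (
    CVResults,
    TrainOptions,
    cross_validate,
    evaluate,
    smote_oversample,
    train_network,
)

__all__ = [
    "AttributionResult",
    "balanced_reference",
    "attribute_genes",
    "attribute_pathway_nodes",
    "importance_scores",
    "cross_validated_importance",
    "known_gene_test",
    "RankSumResult",
    "size_importance_correlation",
    "feature_selection_experiment",
]

_RESCALE_TOL = 1e-7


@dataclass
class AttributionResult:
    """Per-sample, per-node contributions against a reference distribution.

    ``C[s, i]`` is node i's contribution for evaluation sample s; rows sum to
    ``y[s] - y_ref`` (summation-to-delta).  ``n_primary`` marks how many
    leading nodes belong to the layer of interest when the attribution spans
    a concatenated layer (pathway nodes before fully connected nodes).
    """

    node_ids: list[str]
    C: np.ndarray
    y: np.ndarray
    y_ref: float
    n_primary: int | None = None

    @property
    def primary(self) -> np.ndarray:
        """Rows of ``C`` restricted to the primary nodes (all, if unset)."""
        return self.C if self.n_primary is None else self.C[:, : self.n_primary]

    def completeness_error(self) -> np.ndarray:
        """|sum_i C_i - (y - y_ref)| per sample."""
        return np.abs(self.C.sum(axis=1) - (self.y - self.y_ref))

    def check_completeness(self, tol: float = 1e-3) -> None:
        err = self.completeness_error()
        bound = tol * np.maximum(1.0, np.abs(self.y - self.y_ref))
        if np.any(err > bound):
            worst = int(np.argmax(err - bound))
            raise AssertionError(
                f"summation-to-delta violated: sample {worst} error {err[worst]:.3e}"
            )

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.C).mean(axis=0)


def balanced_reference(
    model,
    X_train: np.ndarray,
    y_train: np.ndarray,
    size: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Class-balanced random reference set and its mean case-class output.

    Draws size/2 samples per class without replacement.  ``size=None`` uses
    100, shrunk to what the smaller class supports.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    counts = np.bincount(y_train, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present in the training data")
    cap = 2 * int(counts.min())
    if size is None:
        size = min(100, cap)
        size -= size % 2
    if size > cap:
        raise ValueError(f"size={size} exceeds 2 * min class count ({cap})")
    if size < 2:
        raise ValueError("reference size must be >= 2")
    half = size // 2
    rng = np.random.default_rng(seed)
    rows = []
    for cls in (0, 1):
        idx = np.flatnonzero(y_train == cls)
        rows.append(rng.choice(idx, size=half, replace=False))
    X_ref = X_train[np.concatenate(rows)]
    y_bar = float(np.mean(model.predict_case_proba(X_ref)))
    return X_ref, y_bar


# --------------------------------------------------------------------------
# multiplier propagation primitives (all arrays broadcast to (E, R, nodes))
# --------------------------------------------------------------------------


def _rescale(m_out, z_x, z_r, a_x, a_r, deriv_x):
    """Elementwise rescale rule: multiply by delta-out/delta-in, or the
    derivative where delta-in is below tolerance."""
    dz = z_x - z_r
    da = a_x - a_r
    slope = np.where(np.abs(dz) > _RESCALE_TOL, da / np.where(dz == 0, 1.0, dz), deriv_x)
    return m_out * slope


def _ln_multipliers(m_out, a_x, a_r, gamma):
    """Exact summation-to-delta multipliers through layer normalization.

    With z = a - mean(a) and s = sqrt(mean(z^2) + eps) for sample (z_x, s_x)
    and reference (z_r, s_r):

        delta_y_j = g_j * dz_j / s_x
                    - g_j * z_r_j * mean_i((z_x + z_r)_i dz_i) / (s_x s_r (s_x + s_r))

    which is linear in dz with coefficients depending on both endpoints, so
    transposing it propagates multipliers without approximation.  Centering
    is symmetric, hence self-transposed.
    """
    n = a_x.shape[-1]
    z_x = a_x - a_x.mean(axis=-1, keepdims=True)  # (E, 1, n)
    z_r = a_r - a_r.mean(axis=-1, keepdims=True)  # (1, R, n)
    s_x = np.sqrt((z_x * z_x).mean(axis=-1, keepdims=True) + LN_EPS)
    s_r = np.sqrt((z_r * z_r).mean(axis=-1, keepdims=True) + LN_EPS)
    S = (m_out * gamma * z_r).sum(axis=-1, keepdims=True)  # (E, R, 1)
    m_z = m_out * gamma / s_x - S * (z_x + z_r) / (n * s_x * s_r * (s_x + s_r))
    return m_z - m_z.mean(axis=-1, keepdims=True)


def _head_multipliers(model, H_x, H_r, zh_x, zh_r):
    """Multipliers from the case-class probability down to the concatenated
    (post-dropout-identity) layer, shared by both architectures' heads."""
    p = model.params
    w_d = p["Wo"][1] - p["Wo"][0]
    d_x = H_x @ w_d + (p["bo"][1] - p["bo"][0])  # (E,)
    d_r = H_r @ w_d + (p["bo"][1] - p["bo"][0])  # (R,)
    y_x = 1.0 / (1.0 + np.exp(-d_x))
    y_r = 1.0 / (1.0 + np.exp(-d_r))
    m_d = _rescale(
        np.ones((d_x.size, d_r.size)),
        d_x[:, None], d_r[None, :], y_x[:, None], y_r[None, :],
        (y_x * (1 - y_x))[:, None],
    )  # (E, R)
    m_h = m_d[:, :, None] * w_d[None, None, :]
    m_zh = _rescale(
        m_h, zh_x[:, None, :], zh_r[None, :, :], H_x[:, None, :], H_r[None, :, :],
        (1.0 - H_x * H_x)[:, None, :],
    )
    m_concat = np.einsum("erh,hc->erc", m_zh, p["Wh"])
    return m_concat, y_x, y_r


def _pinnet_layer_values(model: PINNet, X: np.ndarray):
    """Branch and head activations in evaluation mode."""
    p = model.params
    zp = (X @ model.effective_pathway_weights.T) * model.u
    P = np.tanh(zp)
    zf = X @ p["Wf"].T + p["bf"]
    F = np.tanh(zf)
    Pn = _affine_ln(P, p["ln_p_gamma"], p["ln_p_beta"])
    Fn = _affine_ln(F, p["ln_f_gamma"], p["ln_f_beta"])
    zh = np.concatenate([Pn, Fn], axis=1) @ p["Wh"].T + p["bh"]
    H = np.tanh(zh)
    return {"zp": zp, "P": P, "zf": zf, "F": F, "zh": zh, "H": H}


def _affine_ln(x, gamma, beta):
    mu = x.mean(axis=-1, keepdims=True)
    z = x - mu
    s = np.sqrt((z * z).mean(axis=-1, keepdims=True) + LN_EPS)
    return gamma * z / s + beta


def _pinnet_concat_multipliers(model: PINNet, ax, ar):
    """Multipliers from output to the pre-layer-norm (p, f) activations."""
    p = model.params
    m = model.config.n_pathways
    m_concat, y_x, y_r = _head_multipliers(model, ax["H"], ar["H"], ax["zh"], ar["zh"])
    m_P = _ln_multipliers(
        m_concat[:, :, :m], ax["P"][:, None, :], ar["P"][None, :, :], p["ln_p_gamma"]
    )
    m_F = _ln_multipliers(
        m_concat[:, :, m:], ax["F"][:, None, :], ar["F"][None, :, :], p["ln_f_gamma"]
    )
    return m_P, m_F, y_x, y_r


def _check_eval_inputs(model, X_eval, reference):
    X_eval = np.atleast_2d(np.asarray(X_eval, dtype=np.float64))
    X_ref = np.atleast_2d(np.asarray(reference, dtype=np.float64))
    if X_eval.shape[1] != X_ref.shape[1]:
        raise ValueError("evaluation and reference matrices disagree on gene count")
    return X_eval, X_ref


def attribute_genes(
    model: PINNet | BaselineDNN,
    X_eval: np.ndarray,
    reference: np.ndarray,
    node_ids: list[str] | None = None,
    block_size: int = 32,
) -> AttributionResult:
    """Gene-level contributions to the case-class probability.

    ``reference`` is the balanced reference matrix; contributions are
    averaged over all (sample, reference) pairs.
    """
    X_eval, X_ref = _check_eval_inputs(model, X_eval, reference)
    n = X_eval.shape[1]
    if node_ids is None:
        node_ids = (
            list(model.mask.gene_ids) if isinstance(model, PINNet) else [f"g{i}" for i in range(n)]
        )
    C = np.empty((X_eval.shape[0], n))
    ys = np.empty(X_eval.shape[0])
    y_ref = None
    for start in range(0, X_eval.shape[0], block_size):
        Xb = X_eval[start : start + block_size]
        if isinstance(model, PINNet):
            m_x, y_x, y_r = _pinnet_gene_multipliers(model, Xb, X_ref)
        else:
            m_x, y_x, y_r = _dnn_gene_multipliers(model, Xb, X_ref)
        contrib = m_x * (Xb[:, None, :] - X_ref[None, :, :])
        C[start : start + block_size] = contrib.mean(axis=1)
        ys[start : start + block_size] = y_x
        y_ref = float(np.mean(y_r))
    if not np.all(np.isfinite(C)):
        bad = node_ids[int(np.argwhere(~np.isfinite(C))[0][1])]
        raise FloatingPointError(f"non-finite attribution for node {bad!r}")
    return AttributionResult(node_ids, C, ys, y_ref)


def _pinnet_gene_multipliers(model: PINNet, Xb, X_ref):
    ax = _pinnet_layer_values(model, Xb)
    ar = _pinnet_layer_values(model, X_ref)
    m_P, m_F, y_x, y_r = _pinnet_concat_multipliers(model, ax, ar)
    m_zp = _rescale(
        m_P, ax["zp"][:, None, :], ar["zp"][None, :, :],
        ax["P"][:, None, :], ar["P"][None, :, :],
        (1.0 - ax["P"] ** 2)[:, None, :],
    ) * model.u
    m_zf = _rescale(
        m_F, ax["zf"][:, None, :], ar["zf"][None, :, :],
        ax["F"][:, None, :], ar["F"][None, :, :],
        (1.0 - ax["F"] ** 2)[:, None, :],
    )
    m_x = np.einsum("erm,mn->ern", m_zp, model.effective_pathway_weights)
    m_x += np.einsum("erf,fn->ern", m_zf, model.params["Wf"])
    return m_x, y_x, y_r


def _dnn_layer_values(model: BaselineDNN, X):
    p = model.params
    z1 = X @ p["W1"].T + p["b1"]
    A = np.tanh(z1)
    An = _affine_ln(A, p["ln_gamma"], p["ln_beta"])
    zh = An @ p["Wh"].T + p["bh"]
    return {"z1": z1, "A": A, "zh": zh, "H": np.tanh(zh)}


def _dnn_gene_multipliers(model: BaselineDNN, Xb, X_ref):
    p = model.params
    ax = _dnn_layer_values(model, Xb)
    ar = _dnn_layer_values(model, X_ref)
    m_concat, y_x, y_r = _head_multipliers(model, ax["H"], ar["H"], ax["zh"], ar["zh"])
    m_A = _ln_multipliers(m_concat, ax["A"][:, None, :], ar["A"][None, :, :], p["ln_gamma"])
    m_z1 = _rescale(
        m_A, ax["z1"][:, None, :], ar["z1"][None, :, :],
        ax["A"][:, None, :], ar["A"][None, :, :],
        (1.0 - ax["A"] ** 2)[:, None, :],
    )
    return np.einsum("erh,hn->ern", m_z1, p["W1"]), y_x, y_r


def attribute_pathway_nodes(
    model: PINNet,
    X_eval: np.ndarray,
    reference: np.ndarray,
    block_size: int = 32,
) -> AttributionResult:
    """Contributions of pathway-layer nodes, with the branch activations
    (p, f) treated as the input layer of the downstream sub-network.

    Summation-to-delta holds over the full concatenated layer; the pathway
    rows are the leading ``n_primary`` columns (see ``.primary``).
    """
    if not isinstance(model, PINNet):
        raise TypeError("pathway-node attribution requires the pathway-masked model")
    X_eval, X_ref = _check_eval_inputs(model, X_eval, reference)
    m = model.config.n_pathways
    node_ids = list(model.mask.pathway_names) + [
        f"fc{i}" for i in range(model.config.n_fc_nodes)
    ]
    E = X_eval.shape[0]
    C = np.empty((E, len(node_ids)))
    ys = np.empty(E)
    ar = _pinnet_layer_values(model, X_ref)
    for start in range(0, E, block_size):
        Xb = X_eval[start : start + block_size]
        axv = _pinnet_layer_values(model, Xb)
        m_P, m_F, y_x, y_r = _pinnet_concat_multipliers(model, axv, ar)
        dP = axv["P"][:, None, :] - ar["P"][None, :, :]
        dF = axv["F"][:, None, :] - ar["F"][None, :, :]
        C[start : start + block_size, :m] = (m_P * dP).mean(axis=1)
        C[start : start + block_size, m:] = (m_F * dF).mean(axis=1)
        ys[start : start + block_size] = y_x
    y_ref = float(np.mean(1.0 / (1.0 + np.exp(-(ar["H"] @ (model.params["Wo"][1] - model.params["Wo"][0]) + model.params["bo"][1] - model.params["bo"][0])))))
    if not np.all(np.isfinite(C)):
        bad = node_ids[int(np.argwhere(~np.isfinite(C))[0][1])]
        raise FloatingPointError(f"non-finite attribution for node {bad!r}")
    return AttributionResult(node_ids, C, ys, y_ref, n_primary=m)


# --------------------------------------------------------------------------
# importance scores and downstream analyses
# --------------------------------------------------------------------------


def importance_scores(per_fold: list[AttributionResult]) -> pd.DataFrame:
    """Cross-fold importance table.

    Per fold: score nodes by mean |contribution| over that fold's evaluated
    samples, z-score across nodes; the importance score is the mean z-score
    over folds.  Restricted to primary nodes when the attribution spans a
    concatenated layer.
    """
    if not per_fold:
        raise ValueError("need at least one fold")
    ids0 = (
        per_fold[0].node_ids[: per_fold[0].n_primary]
        if per_fold[0].n_primary is not None
        else per_fold[0].node_ids
    )
    cols = {}
    for k, res in enumerate(per_fold):
        ids = res.node_ids[: res.n_primary] if res.n_primary is not None else res.node_ids
        if ids != ids0:
            raise ValueError("folds disagree on the node set")
        s = np.abs(res.primary).mean(axis=0)
        sd = s.std()
        if sd == 0:
            raise ValueError(f"fold {k}: mean absolute attribution is constant across nodes")
        cols[f"fold_{k}"] = (s - s.mean()) / sd
    table = pd.DataFrame(cols, index=pd.Index(ids0, name="node_id"))
    table["importance_score"] = table.mean(axis=1)
    return table


def cross_validated_importance(
    dataset: ExpressionDataset,
    mask: MaskMatrix | None,
    grid,
    opts: TrainOptions | None = None,
    seed: int = 0,
    model_kind: str = "pinnet",
    reference_size: int | None = None,
    n_folds: int = 10,
    pathway_nodes: bool = False,
) -> tuple[pd.DataFrame, CVResults]:
    """Train by cross-validation and build the importance table from each
    fold's model, evaluated on that fold's test samples with a balanced
    reference drawn from its training samples."""
    cv = cross_validate(
        dataset, mask, grid=grid, opts=opts, seed=seed,
        model_kind=model_kind, n_folds=n_folds,
    )
    X, y = dataset.X(), dataset.y()
    per_fold = []
    for split, net in zip(cv.splits, cv.models):
        ref, _ = balanced_reference(
            net, X[split.train_ids], y[split.train_ids],
            size=reference_size, seed=derive_seed(seed, "reference", split.fold_index),
        )
        if pathway_nodes:
            per_fold.append(attribute_pathway_nodes(net, X[split.test_ids], ref))
        else:
            per_fold.append(
                attribute_genes(net, X[split.test_ids], ref, node_ids=dataset.gene_ids)
            )
    return importance_scores(per_fold), cv


@dataclass
class RankSumResult:
    U: float
    p_one_sided: float  # known > rest
    p_two_sided: float
    direction: str  # 'known_higher' or 'known_lower'


def known_gene_test(table: pd.DataFrame, known) -> RankSumResult:
    """Two-sample rank-sum comparison of importance scores, known vs rest.

    Exact null enumeration below 25 total observations without ties,
    otherwise the normal approximation with tie correction.
    """
    known = set(known)
    scores = table["importance_score"]
    in_known = scores.index.isin(known)
    a = scores[in_known].to_numpy()
    b = scores[~in_known].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both the known group and the background must be non-empty")
    pooled = np.concatenate([a, b])
    method = "exact" if (pooled.size < 25 and np.unique(pooled).size == pooled.size) else "asymptotic"
    u_greater = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    u_two = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = "known_higher" if np.median(a) >= np.median(b) else "known_lower"
    return RankSumResult(float(u_greater.statistic), float(u_greater.pvalue),
                         float(u_two.pvalue), direction)


def size_importance_correlation(mask: MaskMatrix, pathway_table: pd.DataFrame) -> float:
    """Pearson correlation between pathway sizes (mask row sums) and pathway
    importance scores (signed; callers typically report |r|)."""
    if mask.n_pathways < 3:
        raise ValueError("need at least 3 pathways for a correlation")
    scores = pathway_table["importance_score"].reindex(mask.pathway_names)
    if scores.isna().any():
        raise ValueError("pathway importance table does not cover the mask's pathways")
    r, _ = stats.pearsonr(mask.sizes, scores.to_numpy())
    return float(r)


def feature_selection_experiment(
    dataset: ExpressionDataset,
    mask: MaskMatrix,
    fraction: float = 0.10,
    seed: int = 0,
    opts: TrainOptions | None = None,
    grid=((64, 1e-3),),
    mlp_lr: float = 1e-3,
    n_repeats: int = 10,
) -> pd.DataFrame:
    """Importance-guided feature selection versus random and all-gene arms.

    The samples are split into ``n_repeats`` stratified parts.  In repeat i,
    eight parts train the pathway-masked model, one part (the feature
    selection set) ranks genes by single-model importance, and the held-out
    part scores a freshly trained MLP with layer widths {n, n/2, n/4, 2} on
    (a) the top ``fraction`` genes, (b) a size-matched random gene set, and
    (c) all genes.  Ties at the selection boundary are all kept.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    opts = opts or TrainOptions()
    X, y = dataset.X(), dataset.y()
    gene_ids = np.asarray(dataset.gene_ids)
    n_top = int(round(fraction * len(gene_ids)))
    if n_top < 2:
        raise ValueError(f"fraction {fraction} selects {n_top} gene(s); need >= 2")
    skf = StratifiedKFold(n_splits=n_repeats, shuffle=True,
                          random_state=derive_seed(seed, "fs_parts"))
    parts = [test for _, test in skf.split(np.zeros_like(y), y)]
    rows = []
    rng = np.random.default_rng(derive_seed(seed, "fs_random_arm"))
    for i in range(n_repeats):
        test_idx = parts[i]
        sel_idx = parts[(i + 1) % n_repeats]
        train_idx = np.concatenate([parts[j] for j in range(n_repeats) if j not in (i, (i + 1) % n_repeats)])
        ranked = _rank_genes_one_model(
            X, y, train_idx, sel_idx, mask, grid, opts, derive_seed(seed, "fs_rank", i)
        )
        cut = ranked.iloc[n_top - 1]
        selected = ranked.index[ranked >= cut].tolist()  # keep boundary ties
        random_set = list(rng.choice(gene_ids, size=len(selected), replace=False))
        arms = {"selected": selected, "random": random_set, "all": list(gene_ids)}
        col_of = {g: j for j, g in enumerate(dataset.gene_ids)}
        for arm, genes in arms.items():
            cols = [col_of[g] for g in genes]
            auc = _mlp_arm_auc(
                X[:, cols], y, train_idx, test_idx, opts, mlp_lr,
                derive_seed(seed, "fs_mlp", i, arm),
            )
            rows.append({"repeat": i, "arm": arm, "auc": auc, "n_genes": len(genes)})
    return pd.DataFrame(rows)


def _rank_genes_one_model(X, y, train_idx, sel_idx, mask, grid, opts, seed):
    """Train on the training parts, rank genes by |mean contribution| on the
    selection part (descending), returned as a Series gene -> score."""
    inner = StratifiedKFold(n_splits=8, shuffle=True, random_state=derive_seed(seed, "val"))
    tr_pos, val_pos = next(inner.split(np.zeros(len(train_idx)), y[train_idx]))
    tr, val = train_idx[tr_pos], train_idx[val_pos]
    X_bal, y_bal = smote_oversample(X[tr], y[tr], k_neighbors=opts.k_neighbors,
                                    seed=derive_seed(seed, "smote"))
    best = None
    for gi, (width, lr) in enumerate(grid):
        cfg = PINNetConfig(
            n_genes=X.shape[1], n_pathways=mask.n_pathways, n_fc_nodes=width,
            dropout_rate=opts.dropout_rate, norm_mode=opts.norm_mode,
            seed=derive_seed(seed, "init", gi),
        )
        net = PINNet(cfg, mask)
        fit = train_network(
            net, X_bal, y_bal, X[val], y[val], lr=lr, max_epochs=opts.max_epochs,
            batch_size=opts.batch_size, patience=opts.patience, seed=derive_seed(seed, "fit", gi),
        )
        if best is None or fit.best_val_auc > best.best_val_auc:
            best = fit
    ref, _ = balanced_reference(best.model, X[tr], y[tr], seed=derive_seed(seed, "ref"))
    attr = attribute_genes(best.model, X[sel_idx], ref)
    s = pd.Series(np.abs(attr.C).mean(axis=0), index=attr.node_ids)
    return s.sort_values(ascending=False, kind="stable")


def _mlp_arm_auc(X_sub, y, train_idx, test_idx, opts, lr, seed):
    n = X_sub.shape[1]
    inner = StratifiedKFold(n_splits=8, shuffle=True, random_state=derive_seed(seed, "val"))
    tr_pos, val_pos = next(inner.split(np.zeros(len(train_idx)), y[train_idx]))
    tr, val = train_idx[tr_pos], train_idx[val_pos]
    X_bal, y_bal = smote_oversample(X_sub[tr], y[tr], k_neighbors=opts.k_neighbors,
                                    seed=derive_seed(seed, "smote"))
    net = MLP([n, max(n // 2, 2), max(n // 4, 2), 2],
              dropout_rate=opts.dropout_rate, seed=derive_seed(seed, "init"))
    train_network(
        net, X_bal, y_bal, X_sub[val], y[val], lr=lr, max_epochs=opts.max_epochs,
        batch_size=opts.batch_size, patience=opts.patience, seed=derive_seed(seed, "fit"),
    )
    auc, _ = evaluate(net, X_sub[test_idx], y[test_idx])
    return auc
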