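"""Training: SMOTE balancing, stratified cross-validation, grid search,
AUC-based early stopping, and test-set evaluation.

The protocol is stratified 10-fold cross-validation with an 8:1:1
train/validation/test split per fold.  The training portion of each fold is
SMOTE-oversampled to exact class balance, the network is trained with Adam
(mini-batch 64, cross-entropy), the learning rate is halved when the
validation AUC plateaus, and training stops once the validation AUC has not
improved for 10 consecutive epochs; the best-epoch weights are restored.
Hyperparameters (fully connected branch width and learning rate) are chosen
per fold by validation AUC; test AUC and F1 are computed once, afterwards,
on the untouched test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from ._utils import derive_seed
from .model import BaselineDNN, MLP, PINNet, PINNetConfig
from .pathways import MaskMatrix
from .preprocess import ExpressionDataset

__all__ = [
    "DEFAULT_GRID",
    "FoldSplit",
    "FitResult",
    "TrainReport",
    "CVResults",
    "TrainOptions",
    "stratified_10fold",
    "smote_oversample",
    "train_network",
    "train_fold",
    "evaluate",
    "cross_validate",
]

# paper-scale grid: fully-connected branch width x learning rate
DEFAULT_GRID: tuple[tuple[int, float], ...] = tuple(
    (n_fc, lr) for n_fc in (32, 64, 128) for lr in (0.0001, 0.0005, 0.001)
)


@dataclass(frozen=True)
class FoldSplit:
    """One fold's 8:1:1 stratified partition (positional sample indices)."""

    fold_index: int
    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("fold partitions overlap")


def stratified_10fold(labels: np.ndarray, seed: int, n_folds: int = 10) -> list[FoldSplit]:
    """Stratified folds: fold k's test set is the k-th partition; the
    validation set is one stratified 1/(n_folds-1) slice of the remainder."""
    y = np.asarray(labels, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= {n_folds} for "
            f"{n_folds}-fold stratification"
        )
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=derive_seed(seed, "outer"))
    splits: list[FoldSplit] = []
    for k, (rest, test) in enumerate(outer.split(np.zeros_like(y), y)):
        inner = StratifiedKFold(
            n_splits=n_folds - 1, shuffle=True, random_state=derive_seed(seed, "inner", k)
        )
        tr_pos, val_pos = next(inner.split(np.zeros(len(rest)), y[rest]))
        splits.append(FoldSplit(k, rest[tr_pos], rest[val_pos], test))
    return splits


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthesizing minority samples on segments between a
    minority sample and one of its k nearest minority neighbors (Euclidean).

    Originals are kept unmodified; each synthetic point is
    ``alpha * x_i + (1 - alpha) * x_j`` with ``alpha ~ U[0, 1]``.
    Already-balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    X_min = X[y == minority]
    if X_min.shape[0] <= k_neighbors:
        raise ValueError(
            f"minority class has {X_min.shape[0]} samples, <= k_neighbors="
            f"{k_neighbors}; use a smaller k"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    # drop self-neighbor in column 0
    neighbor_idx = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, X_min.shape[0], size=n_needed)
    pick = rng.integers(0, k_neighbors, size=n_needed)
    alpha = rng.random(n_needed)[:, None]
    partner = neighbor_idx[base, pick]
    synth = alpha * X_min[base] + (1.0 - alpha) * X_min[partner]
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=np.int64)])
    return X_out, y_out


def evaluate(model, X_test: np.ndarray, y_test: np.ndarray) -> tuple[float, float]:
    """Test AUC (case-class probability) and F1 for the case class at 0.5."""
    y_test = np.asarray(y_test, dtype=np.int64)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set contains a single class; AUC undefined")
    scores = model.predict_case_proba(np.asarray(X_test, dtype=np.float64))
    auc = float(roc_auc_score(y_test, scores))
    f1 = float(f1_score(y_test, (scores >= 0.5).astype(int), pos_label=1))
    return auc, f1


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class FitResult:
    """Outcome of one training run: history, best epoch, and the model (with
    best-epoch weights restored)."""

    model: object
    epochs_run: int
    best_epoch: int
    best_val_auc: float
    history: pd.DataFrame  # epoch, train_loss, val_auc, lr
    seed: int

    def summary(self) -> str:
        return (
            f"{type(self.model).__name__}: {self.epochs_run} epochs "
            f"(best {self.best_epoch}), val AUC {self.best_val_auc:.4f}"
        )


def train_network(
    model,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float = 1e-3,
    max_epochs: int = 200,
    batch_size: int = 64,
    patience: int = 10,
    scheduler_factor: float = 0.5,
    scheduler_patience: int = 5,
    min_lr: float = 1e-6,
    seed: int = 0,
) -> FitResult:
    """Adam training with validation-AUC early stopping and plateau LR decay.

    Stops once ``patience`` consecutive epochs pass without the validation
    AUC improving; the weights of the best epoch are restored.  Fully
    deterministic for fixed (data, seed).
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    rng = np.random.default_rng(derive_seed(seed, "train_loop"))
    opt = _Adam(model.params, lr)
    best_auc, best_epoch, best_weights = -np.inf, 0, model.get_weights()
    epochs_no_improve = 0
    plateau = 0
    rows = []
    n = X_train.shape[0]
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = model.loss_and_grads(X_train[idx], y_train[idx], rng)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.step(model.params, grads)
            losses.append(loss)
        val_auc = float(roc_auc_score(y_val, model.predict_case_proba(X_val)))
        rows.append((epoch, float(np.mean(losses)), val_auc, opt.lr))
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_weights = model.get_weights()
            epochs_no_improve = 0
            plateau = 0
        else:
            epochs_no_improve += 1
            plateau += 1
            if plateau > scheduler_patience and opt.lr > min_lr:
                opt.lr = max(opt.lr * scheduler_factor, min_lr)
                plateau = 0
            if epochs_no_improve >= patience:
                break
    model.set_weights(best_weights)
    history = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_auc", "lr"])
    return FitResult(model, epoch, best_epoch, best_auc, history, seed)


@dataclass
class TrainOptions:
    """Training-budget knobs shared across folds."""

    max_epochs: int = 200
    batch_size: int = 64
    patience: int = 10
    k_neighbors: int = 5
    dropout_rate: float = 0.3
    norm_mode: str = "inverse_sqrt"
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-6


@dataclass
class TrainReport:
    """Per-fold record: chosen hyperparameters and held-out test metrics."""

    fold_index: int
    best_hyperparams: dict
    epochs_run: int
    best_val_auc: float
    test_auc: float
    test_f1: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "best_hyperparams": self.best_hyperparams,
            "epochs_run": self.epochs_run,
            "best_val_auc": self.best_val_auc,
            "test_auc": self.test_auc,
            "test_f1": self.test_f1,
            "seed": self.seed,
        }


def _make_model(kind: str, n_genes: int, mask, width: int, opts: TrainOptions, seed: int):
    if kind == "pinnet":
        cfg = PINNetConfig(
            n_genes=n_genes, n_pathways=mask.n_pathways, n_fc_nodes=width,
            dropout_rate=opts.dropout_rate, norm_mode=opts.norm_mode, seed=seed,
        )
        return PINNet(cfg, mask)
    if kind == "dnn":
        return BaselineDNN(n_genes, n_hidden1=width, dropout_rate=opts.dropout_rate, seed=seed)
    raise ValueError(f"unknown model kind {kind!r}")


def train_fold(
    dataset: ExpressionDataset,
    split: FoldSplit,
    mask: MaskMatrix | None,
    grid=DEFAULT_GRID,
    opts: TrainOptions | None = None,
    seed: int = 0,
    model_kind: str = "pinnet",
):
    """Grid-search one fold and evaluate the winner on the fold's test split.

    For each (width, learning-rate) grid point the training split is SMOTE
    balanced and the network trained with early stopping on validation AUC;
    the grid point with the best validation AUC is selected and the test
    split is scored once.  Returns ``(TrainReport, fitted model)``.
    """
    opts = opts or TrainOptions()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X, y = dataset.X(), dataset.y()
    X_tr, y_tr = X[split.train_ids], y[split.train_ids]
    X_val, y_val = X[split.val_ids], y[split.val_ids]
    X_te, y_te = X[split.test_ids], y[split.test_ids]
    X_bal, y_bal = smote_oversample(
        X_tr, y_tr, k_neighbors=opts.k_neighbors,
        seed=derive_seed(seed, "smote", split.fold_index),
    )
    best = None
    for gi, (width, lr) in enumerate(grid):
        g_seed = derive_seed(seed, "fit", split.fold_index, gi)
        net = _make_model(model_kind, X.shape[1], mask, width, opts, g_seed)
        try:
            fit = train_network(
                net, X_bal, y_bal, X_val, y_val,
                lr=lr, max_epochs=opts.max_epochs, batch_size=opts.batch_size,
                patience=opts.patience, scheduler_factor=opts.scheduler_factor,
                scheduler_patience=opts.scheduler_patience, min_lr=opts.min_lr,
                seed=g_seed,
            )
        except FloatingPointError:  # diverged grid point: skip, keep searching
            continue
        if best is None or fit.best_val_auc > best[0].best_val_auc:
            best = (fit, {"width": width, "learning_rate": lr})
    if best is None:
        raise RuntimeError("every grid point diverged")
    fit, hyper = best
    test_auc, test_f1 = evaluate(fit.model, X_te, y_te)
    report = TrainReport(
        fold_index=split.fold_index, best_hyperparams=hyper,
        epochs_run=fit.epochs_run, best_val_auc=fit.best_val_auc,
        test_auc=test_auc, test_f1=test_f1, seed=seed,
    )
    return report, fit.model


@dataclass
class CVResults:
    """Cross-validation outcome: per-fold reports, fitted models and splits."""

    reports: list[TrainReport]
    models: list[object]
    splits: list[FoldSplit]
    seed: int
    model_kind: str = "pinnet"
    mask: MaskMatrix | None = None

    @property
    def mean_test_auc(self) -> float:
        return float(np.mean([r.test_auc for r in self.reports]))

    @property
    def mean_test_f1(self) -> float:
        return float(np.mean([r.test_f1 for r in self.reports]))

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.reports])
        hp = pd.json_normalize(df.pop("best_hyperparams"))
        return pd.concat([df, hp], axis=1)


def cross_validate(
    dataset: ExpressionDataset,
    mask: MaskMatrix | None = None,
    grid=DEFAULT_GRID,
    opts: TrainOptions | None = None,
    seed: int = 0,
    model_kind: str = "pinnet",
    n_folds: int = 10,
) -> CVResults:
    """Stratified ``n_folds``-fold cross-validation (8:1:1 per fold at 10)."""
    if model_kind == "pinnet" and mask is None:
        raise ValueError("pathway mask required for the pathway-informed model")
    splits = stratified_10fold(dataset.y(), seed=seed, n_folds=n_folds)
    reports, models = [], []
    for split in splits:
        rep, net = train_fold(
            dataset, split, mask, grid=grid, opts=opts, seed=seed, model_kind=model_kind
        )
        reports.append(rep)
        models.append(net)
    return CVResults(reports, models, splits, seed, model_kind, mask)
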