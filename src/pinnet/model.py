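"""Network architectures: the pathway-masked classifier and dense baselines.

The pathway-informed network takes a gene-expression vector ``g`` (values in
[0, 1]) and feeds it through two parallel branches:

* a pathway branch ``p = tanh(((W_p o M) g) * u)`` whose weight matrix is
  element-wise masked by the binary pathway-membership matrix ``M`` on every
  forward pass, so each pathway node sees only its member genes, and ``u``
  rescales each node by its pathway size;
* a fully connected branch ``f = tanh(W_f g + b_f)`` that can capture signal
  outside the annotated sets.

Both branches are layer-normalized, concatenated, passed through dropout, a
64-unit tanh hidden layer and a 2-logit softmax head.  The case-class
probability is the model output ``o``.

Everything is plain numpy with hand-written gradients; masking inside the
forward pass guarantees that masked effective weights are exactly zero after
any number of optimizer steps (their gradient is identically zero).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from ._utils import check_finite
from .pathways import MaskMatrix, normalization_vector

if TYPE_CHECKING:  # pragma: no cover
    from .train import FitResult

__all__ = [
    "PINNetConfig",
    "PINNet",
    "BaselineDNN",
    "MLP",
    "init_model",
    "build_baseline_dnn",
    "LN_EPS",
]

LN_EPS = 1e-5


def _xavier(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def _ln_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + LN_EPS)
    xhat = xc * inv
    return gamma * xhat + beta, (xhat, inv, gamma)


def _ln_backward(dy: np.ndarray, cache):
    xhat, inv, gamma = cache
    n = xhat.shape[-1]
    dgamma = (dy * xhat).sum(axis=0)
    dbeta = dy.sum(axis=0)
    dxhat = dy * gamma
    dx = (inv / n) * (
        n * dxhat
        - dxhat.sum(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
    )
    return dx, dgamma, dbeta


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _dropout_mask(rng: np.random.Generator, shape, rate: float) -> np.ndarray:
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(np.float64) / keep


@dataclass
class PINNetConfig:
    """Architecture hyperparameters.

    ``n_fc_nodes`` is the width of the fully connected branch (grid-searched
    over {32, 64, 128}); ``n_hidden`` is the fixed 64-unit second hidden
    layer; ``dropout_rate`` applies to the concatenated pathway-layer output
    and the hidden-layer output.
    """

    n_genes: int
    n_pathways: int
    n_fc_nodes: int = 64
    n_hidden: int = 64
    dropout_rate: float = 0.3
    norm_mode: str = "inverse_sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_pathways", "n_fc_nodes", "n_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")


class _SoftmaxNet:
    """Shared plumbing: parameter store, prediction, loss/gradients, fit."""

    params: dict[str, np.ndarray]
    dropout_rate: float

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = weights[k].copy()

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # concrete classes implement _forward_cached / _backward
    def _forward_cached(self, X, training, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def _backward(self, cache, dzo):  # pragma: no cover - interface
        raise NotImplementedError

    def forward(
        self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Class probabilities, shape (batch, 2).  Eval mode is deterministic."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        check_finite(X)
        if training and rng is None:
            rng = np.random.default_rng(0)
        probs, _ = self._forward_cached(X, training, rng)
        return probs

    predict_proba = forward

    def predict_case_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[:, 1]

    def loss_and_grads(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy and gradients for one (dropout-sampled) batch."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if rng is None:
            rng = np.random.default_rng(0)
        probs, cache = self._forward_cached(X, True, rng)
        B = X.shape[0]
        eps = 1e-12
        loss = -float(np.mean(np.log(probs[np.arange(B), y] + eps)))
        dzo = probs.copy()
        dzo[np.arange(B), y] -= 1.0
        dzo /= B
        return loss, self._backward(cache, dzo)

    def fit(self, X_train, y_train, X_val, y_val, **kwargs) -> "FitResult":
        """Train with Adam / plateau scheduler / early stopping on validation
        AUC; returns a :class:`pinnet.train.FitResult` with history and the
        best-epoch weights restored in place."""
        from .train import train_network

        return train_network(self, X_train, y_train, X_val, y_val, **kwargs)


class PINNet(_SoftmaxNet):
    """Pathway-masked two-branch classifier."""

    def __init__(self, config: PINNetConfig, mask: MaskMatrix):
        if mask.n_pathways != config.n_pathways or mask.n_genes != config.n_genes:
            raise ValueError(
                f"mask is {mask.n_pathways}x{mask.n_genes}, config expects "
                f"{config.n_pathways}x{config.n_genes}"
            )
        self.config = config
        self.mask = (
            mask if mask.norm_mode == config.norm_mode else mask.with_norm_mode(config.norm_mode)
        )
        self.M = self.mask.M
        self.u = self.mask.u
        self.dropout_rate = config.dropout_rate
        m, n, nfc, h = config.n_pathways, config.n_genes, config.n_fc_nodes, config.n_hidden
        rng = np.random.default_rng(config.seed)
        self.params = {
            "Wp": _xavier(rng, m, n),  # no bias: p = tanh(u * (Wp o M) g)
            "Wf": _xavier(rng, nfc, n),
            "bf": np.zeros(nfc),
            "ln_p_gamma": np.ones(m),
            "ln_p_beta": np.zeros(m),
            "ln_f_gamma": np.ones(nfc),
            "ln_f_beta": np.zeros(nfc),
            "Wh": _xavier(rng, h, m + nfc),
            "bh": np.zeros(h),
            "Wo": _xavier(rng, 2, h),
            "bo": np.zeros(2),
        }

    # -- branch views used by the attribution engine and tests ---------------
    @property
    def effective_pathway_weights(self) -> np.ndarray:
        """(W_p o M): exactly zero wherever M is zero."""
        return self.params["Wp"] * self.M

    def forward_pathway(self, g: np.ndarray) -> np.ndarray:
        """Pathway-node activations p = tanh(u * (W_p o M) g)."""
        g = np.asarray(g, dtype=np.float64)
        single = g.ndim == 1
        g = np.atleast_2d(g)
        check_finite(g)
        p = np.tanh((g @ self.effective_pathway_weights.T) * self.u)
        return p[0] if single else p

    def forward_fc(self, g: np.ndarray) -> np.ndarray:
        """Fully-connected-branch activations f = tanh(W_f g + b_f)."""
        g = np.asarray(g, dtype=np.float64)
        single = g.ndim == 1
        g = np.atleast_2d(g)
        check_finite(g)
        f = np.tanh(g @ self.params["Wf"].T + self.params["bf"])
        return f[0] if single else f

    def branch_activations(self, X: np.ndarray) -> dict[str, np.ndarray]:
        """Pre- and post-activation values of both branches (eval mode)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        zp = (X @ self.effective_pathway_weights.T) * self.u
        zf = X @ self.params["Wf"].T + self.params["bf"]
        return {"zp": zp, "P": np.tanh(zp), "zf": zf, "F": np.tanh(zf)}

    def _forward_cached(self, X, training, rng):
        p = self.params
        Weff = p["Wp"] * self.M
        q = X @ Weff.T
        zp = q * self.u
        P = np.tanh(zp)
        zf = X @ p["Wf"].T + p["bf"]
        F = np.tanh(zf)
        Pn, cp = _ln_forward(P, p["ln_p_gamma"], p["ln_p_beta"])
        Fn, cf = _ln_forward(F, p["ln_f_gamma"], p["ln_f_beta"])
        C = np.concatenate([Pn, Fn], axis=1)
        if training and self.dropout_rate > 0:
            d1 = _dropout_mask(rng, C.shape, self.dropout_rate)
        else:
            d1 = None
        C1 = C * d1 if d1 is not None else C
        zh = C1 @ p["Wh"].T + p["bh"]
        H = np.tanh(zh)
        if training and self.dropout_rate > 0:
            d2 = _dropout_mask(rng, H.shape, self.dropout_rate)
        else:
            d2 = None
        H1 = H * d2 if d2 is not None else H
        zo = H1 @ p["Wo"].T + p["bo"]
        probs = _softmax(zo)
        cache = (X, P, F, cp, cf, C1, d1, H, H1, d2)
        return probs, cache

    def _backward(self, cache, dzo):
        p = self.params
        X, P, F, cp, cf, C1, d1, H, H1, d2 = cache
        m = self.config.n_pathways
        g = {}
        g["Wo"] = dzo.T @ H1
        g["bo"] = dzo.sum(axis=0)
        dH1 = dzo @ p["Wo"]
        dH = dH1 * d2 if d2 is not None else dH1
        dzh = dH * (1.0 - H * H)
        g["Wh"] = dzh.T @ C1
        g["bh"] = dzh.sum(axis=0)
        dC1 = dzh @ p["Wh"]
        dC = dC1 * d1 if d1 is not None else dC1
        dP_, g["ln_p_gamma"], g["ln_p_beta"] = _ln_backward(dC[:, :m], cp)
        dF_, g["ln_f_gamma"], g["ln_f_beta"] = _ln_backward(dC[:, m:], cf)
        dzp = dP_ * (1.0 - P * P) * self.u
        g["Wp"] = (dzp.T @ X) * self.M  # masked entries get exactly zero gradient
        dzf = dF_ * (1.0 - F * F)
        g["Wf"] = dzf.T @ X
        g["bf"] = dzf.sum(axis=0)
        return g

    # -- checkpointing --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "kind": "PINNet",
            "config": asdict(self.config),
            "mask_sha": _mask_hash(self.M),
            "pathway_names": self.mask.pathway_names,
            "gene_ids": self.mask.gene_ids,
        }
        np.savez(path, __meta__=json.dumps(meta), M=self.M, u=self.u, **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "PINNet":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            cfg = PINNetConfig(**meta["config"])
            mask = MaskMatrix(
                z["M"], meta["pathway_names"], meta["gene_ids"],
                normalization_vector(z["M"], cfg.norm_mode), cfg.norm_mode,
            )
            model = cls(cfg, mask)
            model.set_weights({k: z[k] for k in model.params})
        return model


def _mask_hash(M: np.ndarray) -> str:
    import hashlib

    return hashlib.sha256(np.ascontiguousarray(M.astype(np.int8)).tobytes()).hexdigest()[:16]


class BaselineDNN(_SoftmaxNet):
    """Unmasked baseline: the same pipeline with the pathway branch replaced
    by one fully connected first layer (tanh, layer norm, dropout, 64-unit
    hidden layer, softmax head)."""

    def __init__(
        self,
        n_genes: int,
        n_hidden1: int = 128,
        n_hidden2: int = 64,
        dropout_rate: float = 0.3,
        seed: int = 0,
    ):
        if n_genes < 1 or n_hidden1 < 1 or n_hidden2 < 1:
            raise ValueError("layer widths must be >= 1")
        self.n_genes, self.n_hidden1, self.n_hidden2 = n_genes, n_hidden1, n_hidden2
        self.dropout_rate = dropout_rate
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": _xavier(rng, n_hidden1, n_genes),
            "b1": np.zeros(n_hidden1),
            "ln_gamma": np.ones(n_hidden1),
            "ln_beta": np.zeros(n_hidden1),
            "Wh": _xavier(rng, n_hidden2, n_hidden1),
            "bh": np.zeros(n_hidden2),
            "Wo": _xavier(rng, 2, n_hidden2),
            "bo": np.zeros(2),
        }

    def _forward_cached(self, X, training, rng):
        p = self.params
        z1 = X @ p["W1"].T + p["b1"]
        A = np.tanh(z1)
        An, cl = _ln_forward(A, p["ln_gamma"], p["ln_beta"])
        d1 = _dropout_mask(rng, An.shape, self.dropout_rate) if training and self.dropout_rate > 0 else None
        A1 = An * d1 if d1 is not None else An
        zh = A1 @ p["Wh"].T + p["bh"]
        H = np.tanh(zh)
        d2 = _dropout_mask(rng, H.shape, self.dropout_rate) if training and self.dropout_rate > 0 else None
        H1 = H * d2 if d2 is not None else H
        zo = H1 @ p["Wo"].T + p["bo"]
        return _softmax(zo), (X, A, cl, A1, d1, H, H1, d2)

    def _backward(self, cache, dzo):
        p = self.params
        X, A, cl, A1, d1, H, H1, d2 = cache
        g = {}
        g["Wo"] = dzo.T @ H1
        g["bo"] = dzo.sum(axis=0)
        dH1 = dzo @ p["Wo"]
        dH = dH1 * d2 if d2 is not None else dH1
        dzh = dH * (1.0 - H * H)
        g["Wh"] = dzh.T @ A1
        g["bh"] = dzh.sum(axis=0)
        dA1 = dzh @ p["Wh"]
        dAn = dA1 * d1 if d1 is not None else dA1
        dA, g["ln_gamma"], g["ln_beta"] = _ln_backward(dAn, cl)
        dz1 = dA * (1.0 - A * A)
        g["W1"] = dz1.T @ X
        g["b1"] = dz1.sum(axis=0)
        return g


class MLP(_SoftmaxNet):
    """Plain feed-forward softmax classifier with tanh hidden layers.

    Used by the feature-selection experiment with widths
    ``[n, n//2, n//4, 2]``; dropout after each hidden activation.
    """

    def __init__(self, widths: list[int], dropout_rate: float = 0.3, seed: int = 0):
        if len(widths) < 2 or widths[-1] != 2:
            raise ValueError("widths must end in the 2-logit output layer")
        if any(w < 1 for w in widths):
            raise ValueError("layer widths must be >= 1")
        self.widths = list(widths)
        self.dropout_rate = dropout_rate
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params = {}
        for i in range(len(widths) - 1):
            self.params[f"W{i}"] = _xavier(rng, widths[i + 1], widths[i])
            self.params[f"b{i}"] = np.zeros(widths[i + 1])

    def _forward_cached(self, X, training, rng):
        acts = [X]
        drops = []
        a = X
        L = len(self.widths) - 1
        for i in range(L):
            z = a @ self.params[f"W{i}"].T + self.params[f"b{i}"]
            if i == L - 1:
                return _softmax(z), (acts, drops)
            a = np.tanh(z)
            acts.append(a)
            if training and self.dropout_rate > 0:
                d = _dropout_mask(rng, a.shape, self.dropout_rate)
            else:
                d = None
            drops.append(d)
            if d is not None:
                a = a * d
            acts[-1] = (acts[-1], a)  # (pre-dropout, post-dropout)
        raise AssertionError("unreachable")

    def _backward(self, cache, dzo):
        acts, drops = cache
        L = len(self.widths) - 1
        g = {}
        d_up = dzo
        for i in range(L - 1, -1, -1):
            below = acts[i][1] if i > 0 else acts[0]
            g[f"W{i}"] = d_up.T @ below
            g[f"b{i}"] = d_up.sum(axis=0)
            if i == 0:
                break
            da_post = d_up @ self.params[f"W{i}"]
            a_pre = acts[i][0]
            da = da_post * drops[i - 1] if drops[i - 1] is not None else da_post
            d_up = da * (1.0 - a_pre * a_pre)
        return g


def init_model(config: PINNetConfig, mask: MaskMatrix) -> PINNet:
    """Construct a Xavier-initialized pathway-masked network."""
    return PINNet(config, mask)


def build_baseline_dnn(
    n_genes: int, n_hidden1: int = 128, n_hidden2: int = 64,
    dropout_rate: float = 0.3, seed: int = 0,
) -> BaselineDNN:
    return BaselineDNN(n_genes, n_hidden1, n_hidden2, dropout_rate, seed)
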