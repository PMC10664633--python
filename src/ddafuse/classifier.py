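"""Deep binary classifier mapping a pair feature vector to a score in [0, 1].

The default architecture is a fully-connected stack of 5 hidden layers
of 300 rectified units, each followed by dropout at rate 0.3, ending in
a single sigmoid unit trained with binary cross-entropy and the Nadam
optimizer (Adam with Nesterov momentum) at batch size 64 — the
configuration that drives the published performance of this kind of
pair classifier. A ``conv1d`` variant prepends one 1-D convolution +
max-pooling block over the feature vector before the dense stack, for
experiments with a convolutional front end.

The network, backpropagation and optimizer are implemented directly on
numpy arrays; training is therefore bit-deterministic for a fixed seed
on a fixed platform, with no backend-specific nondeterminism to switch
off.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import ParameterError, ValidationError
from .pair_features import PairFeatureTable
from .similarity import DimensionError

__all__ = ["NetworkConfig", "MLPModel", "build_model", "train", "predict_scores"]

logger = logging.getLogger(__name__)

_EPS = 1e-7  # clip for the cross-entropy log


@dataclass
class NetworkConfig:
    """Hyperparameters of the classifier (defaults = the published setting)."""

    hidden_layers: int = 5
    units_per_layer: int = 300
    dropout_rate: float = 0.3
    batch_size: int = 64
    epochs: int = 200
    optimizer: str = "nadam"
    learning_rate: float = 1e-3
    seed: int = 0
    architecture: str = "dense"  # dense | conv1d
    conv_filters: int = 16
    conv_kernel: int = 3
    pool_size: int = 2
    early_stopping: bool = False
    patience: int = 10
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.hidden_layers < 0:
            raise ParameterError("hidden_layers must be >= 0")
        if self.hidden_layers > 0 and self.units_per_layer < 1:
            raise ParameterError("units_per_layer must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ParameterError("epochs must be >= 0")
        if self.optimizer not in ("nadam", "adam", "sgd"):
            raise ParameterError(f"unknown optimizer {self.optimizer!r}")
        if self.architecture not in ("dense", "conv1d"):
            raise ParameterError(f"unknown architecture {self.architecture!r}")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class MLPModel:
    """Feed-forward binary classifier on numpy arrays.

    Built by :func:`build_model`; holds the weights, the config that
    produced them and, after :func:`train`, the per-epoch history.
    """

    def __init__(self, input_dim: int, cfg: NetworkConfig):
        if input_dim < 1:
            raise ParameterError("input_dim must be >= 1")
        self.cfg = cfg
        self.input_dim = input_dim
        self.history: list[dict] = []
        self.fitted = False
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))

        self.conv_K = None
        self.conv_b = None
        dense_in = input_dim
        if cfg.architecture == "conv1d":
            if input_dim < cfg.conv_kernel:
                raise ParameterError("input_dim smaller than the convolution kernel")
            self.conv_K = rng.normal(
                0.0, np.sqrt(2.0 / cfg.conv_kernel), size=(cfg.conv_kernel, cfg.conv_filters)
            )
            self.conv_b = np.zeros(cfg.conv_filters)
            conv_len = input_dim - cfg.conv_kernel + 1
            pooled_len = max(1, conv_len // cfg.pool_size)
            dense_in = pooled_len * cfg.conv_filters

        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        widths = [dense_in] + [cfg.units_per_layer] * cfg.hidden_layers + [1]
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # -- forward ------------------------------------------------------------

    def _conv_forward(self, X: np.ndarray):
        k, F = self.cfg.conv_kernel, self.cfg.conv_filters
        p = self.cfg.pool_size
        B, d = X.shape
        conv_len = d - k + 1
        patches = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (B, conv_len, k)
        z = patches @ self.conv_K + self.conv_b  # (B, conv_len, F)
        a = np.maximum(z, 0.0)
        pooled_len = max(1, conv_len // p)
        trimmed = a[:, : pooled_len * p].reshape(B, pooled_len, p, F)
        pooled = trimmed.max(axis=2)
        argmax = trimmed.argmax(axis=2)
        flat = pooled.reshape(B, -1)
        cache = (patches, z, trimmed.shape, argmax)
        return flat, cache

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None = None):
        """Forward pass; with ``rng`` set, applies inverted dropout."""
        caches: dict = {"drop": []}
        h = X
        if self.conv_K is not None:
            h, caches["conv"] = self._conv_forward(h)
        caches["acts"] = [h]
        n_layers = len(self.W)
        for li, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if li < n_layers - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and self.cfg.dropout_rate > 0.0:
                    keep = 1.0 - self.cfg.dropout_rate
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                    caches["drop"].append(mask)
                else:
                    caches["drop"].append(None)
            else:
                h = 1.0 / (1.0 + np.exp(-z))
            caches["acts"].append(h)
        return h[:, 0], caches

    # -- backward -----------------------------------------------------------

    def _backward_full(self, X: np.ndarray, y: np.ndarray, caches: dict):
        """Gradients of mean binary cross-entropy w.r.t. all parameters.

        Sigmoid + BCE collapse to dL/dz_out = (p - y)/B at the output
        unit; ReLU and dropout masks are replayed from the caches.
        """
        acts = caches["acts"]
        B = len(y)
        p = acts[-1][:, 0]
        grads_W: list[np.ndarray] = [np.empty(0)] * len(self.W)
        grads_b: list[np.ndarray] = [np.empty(0)] * len(self.b)
        delta = ((p - y) / B)[:, None]
        for li in range(len(self.W) - 1, -1, -1):
            grads_W[li] = acts[li].T @ delta
            grads_b[li] = delta.sum(axis=0)
            delta = delta @ self.W[li].T
            if li > 0:
                delta *= acts[li] > 0.0
                mask = caches["drop"][li - 1]
                if mask is not None:
                    delta *= mask
        grad_K = grad_cb = None
        if self.conv_K is not None:
            patches, z, tshape, argmax = caches["conv"]
            _, pooled_len, psz, F = tshape
            k = self.cfg.conv_kernel
            dpool = delta.reshape(B, pooled_len, F)
            # route pooled gradients to the argmax position of each window
            da = np.zeros((B, pooled_len, psz, F))
            bi, wi, fi = np.meshgrid(
                np.arange(B), np.arange(pooled_len), np.arange(F), indexing="ij"
            )
            da[bi, wi, argmax, fi] = dpool
            da = da.reshape(B, pooled_len * psz, F)
            conv_len = z.shape[1]
            dz = np.zeros_like(z)
            dz[:, : pooled_len * psz] = da
            dz *= z > 0.0
            grad_K = np.einsum("blk,blf->kf", patches, dz)
            grad_cb = dz.sum(axis=(0, 1))
        return grads_W, grads_b, grad_K, grad_cb

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"W{i}": w for i, w in enumerate(self.W)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.b)})
        if self.conv_K is not None:
            arrays["conv_K"] = self.conv_K
            arrays["conv_b"] = self.conv_b
        meta = {"cfg": asdict(self.cfg), "input_dim": self.input_dim, "fitted": self.fitted}
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["_meta"]).decode())
        model = cls(meta["input_dim"], NetworkConfig(**meta["cfg"]))
        model.W = [data[f"W{i}"] for i in range(len(model.W))]
        model.b = [data[f"b{i}"] for i in range(len(model.b))]
        if "conv_K" in data:
            model.conv_K = data["conv_K"]
            model.conv_b = data["conv_b"]
        model.fitted = meta["fitted"]
        return model


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class _Nadam:
    """Nadam / Adam / SGD update on a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], kind: str, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.kind = kind
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.kind == "sgd":
            for p, g in zip(params, grads):
                p -= self.lr * g
            return
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            m_hat = self.m[i] / b1t
            v_hat = self.v[i] / b2t
            if self.kind == "nadam":  # Nesterov look-ahead on the first moment
                m_hat = self.b1 * m_hat + (1.0 - self.b1) * g / b1t
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def build_model(input_dim: int, cfg: NetworkConfig | None = None) -> MLPModel:
    """Construct an untrained classifier for ``input_dim`` features."""
    return MLPModel(input_dim, cfg or NetworkConfig())


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def train(
    model: MLPModel,
    table: PairFeatureTable,
    cfg: NetworkConfig | None = None,
    validation_fraction: float = 0.0,
) -> MLPModel:
    """Fit the classifier on a pair table; returns the fitted model.

    Records per-epoch loss/accuracy on the training rows and, when
    ``validation_fraction > 0``, on a seeded held-out split. With
    ``epochs == 0`` the model is returned untrained with empty history.
    """
    cfg = cfg or model.cfg
    X = np.asarray(table.features, dtype=float)
    y = np.asarray(table.labels, dtype=float)
    if X.shape[1] != model.input_dim:
        raise DimensionError(
            f"table has {X.shape[1]} features, model expects {model.input_dim}"
        )
    if len(np.unique(y)) < 2:
        raise ValidationError("training table contains a single class")
    if not 0.0 <= validation_fraction < 1.0:
        raise ParameterError("validation_fraction must be in [0, 1)")

    ss = np.random.SeedSequence([cfg.seed, 1])
    rng_split, rng_shuffle, rng_drop = (np.random.default_rng(c) for c in ss.spawn(3))

    X_val = y_val = None
    if validation_fraction > 0.0:
        n_val = max(1, int(round(validation_fraction * len(y))))
        perm = rng_split.permutation(len(y))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_val, y_val = X[val_idx], y[val_idx]
        X, y = X[tr_idx], y[tr_idx]

    params = model.W + model.b + ([model.conv_K, model.conv_b] if model.conv_K is not None else [])
    opt = _Nadam(params, cfg.optimizer, cfg.learning_rate)

    n = len(y)
    best_val = np.inf
    stale = 0
    model.history = []
    for epoch in range(cfg.epochs):
        order = rng_shuffle.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _, caches = model._forward(X[idx], rng=rng_drop)
            gW, gb, gK, gcb = model._backward_full(X[idx], y[idx], caches)
            grads = gW + gb + ([gK, gcb] if gK is not None else [])
            opt.step(params, grads)

        p_tr, _ = model._forward(X)
        record = {
            "epoch": epoch,
            "train_loss": _bce(y, p_tr),
            "train_acc": float(np.mean((p_tr >= cfg.threshold) == (y == 1))),
        }
        if X_val is not None:
            p_val, _ = model._forward(X_val)
            record["val_loss"] = _bce(y_val, p_val)
            record["val_acc"] = float(np.mean((p_val >= cfg.threshold) == (y_val == 1)))
        model.history.append(record)
        logger.debug(
            "epoch %d: loss=%.4f acc=%.4f", epoch, record["train_loss"], record["train_acc"]
        )
        if cfg.early_stopping:
            monitored = record.get("val_loss", record["train_loss"])
            if monitored < best_val - 1e-6:
                best_val = monitored
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break

    model.fitted = cfg.epochs > 0
    return model


def predict_scores(model: MLPModel, features: np.ndarray) -> np.ndarray:
    """Association scores in [0, 1], one per feature row; deterministic."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.input_dim:
        raise DimensionError(
            f"feature width {X.shape[1]} does not match model input {model.input_dim}"
        )
    scores, _ = model._forward(X)
    return scores


def history_to_csv(model: MLPModel, path: str | Path) -> None:
    """Export the training history (epoch, losses, accuracies) as CSV."""
    pd.DataFrame(model.history).to_csv(path, index=False)
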