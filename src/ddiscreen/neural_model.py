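"""Multi-label feed-forward classifier over the 86 interaction types.

The network maps a pair feature (two PCA-reduced similarity profiles,
length 2k) through a stack of fully connected hidden layers with batch
normalization and rectified-linear activation to 86 sigmoid outputs, one
per interaction type.  It is trained with binary cross-entropy and the
Adam optimizer.  The gold standard has exactly one type per pair, so the
targets are one-hot vectors consumed as independent binary labels; the
sigmoid head is free to activate several outputs for a pair, which the
downstream analyses rely on.

The implementation is plain NumPy: forward, backward and the optimizer
are written out explicitly, which keeps training bit-reproducible for a
fixed seed and makes the trainable-parameter accounting auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .config import N_TYPES, PCA_DIM

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    The defaults are the full-scale configuration: input 100 (= 2 x 50
    reduced profile), nine hidden layers of 2048 rectified-linear units
    with batch normalization, 86 sigmoid outputs, batch size 1024,
    20 epochs, Adam at learning rate 0.001.
    """

    input_dim: int = 2 * PCA_DIM
    hidden_layers: int = 9
    hidden_units: int = 2048
    output_dim: int = N_TYPES
    batch_norm: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 1024
    epochs: int = 20
    seed: int = 0

    def __post_init__(self):
        for name in ("input_dim", "hidden_layers", "hidden_units", "output_dim",
                     "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Reduced-width configuration for desk-scale runs: the same
        nine-hidden-layer architecture at 256 units."""
        base = dict(hidden_units=256, batch_size=256)
        base.update(overrides)
        return cls(**base)


def count_parameters(cfg: ModelConfig) -> int:
    """Trainable parameter count of the architecture, by walking the
    layer shapes.

    Dense layers contribute fan_in * fan_out + fan_out; each hidden
    layer's batch normalization contributes 2 * hidden_units (scale and
    shift; running statistics are not trainable).
    """
    dims = [cfg.input_dim] + [cfg.hidden_units] * cfg.hidden_layers + [cfg.output_dim]
    total = sum(din * dout + dout for din, dout in zip(dims[:-1], dims[1:]))
    if cfg.batch_norm:
        total += 2 * cfg.hidden_units * cfg.hidden_layers
    return total


@dataclass
class TrainingHistory:
    """Per-epoch loss and categorical accuracy for train/validation."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "epoch": np.arange(1, len(self) + 1),
            "train_loss": self.train_loss, "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss, "val_accuracy": self.val_accuracy,
        })


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))


class InteractionClassifier:
    """The multi-label network itself.

    Weight layout: ``W[i], b[i]`` for layer i over dims
    ``[input, hidden * L, output]``; hidden layers additionally carry
    batch-norm ``gamma[i], beta[i]`` and (non-trainable) running mean /
    variance used at inference time.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dims = [cfg.input_dim] + [cfg.hidden_units] * cfg.hidden_layers + [cfg.output_dim]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout))
                  for din, dout in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(dout) for dout in dims[1:]]
        nh = cfg.hidden_layers
        self.gamma = [np.ones(cfg.hidden_units) for _ in range(nh)]
        self.beta = [np.zeros(cfg.hidden_units) for _ in range(nh)]
        self.run_mean = [np.zeros(cfg.hidden_units) for _ in range(nh)]
        self.run_var = [np.ones(cfg.hidden_units) for _ in range(nh)]
        self._rng = rng
        self._adam_state = None

    # -- parameter accounting -------------------------------------------------

    def _trainable_arrays(self) -> list[np.ndarray]:
        arrays = list(self.W) + list(self.b)
        if self.cfg.batch_norm:
            arrays += list(self.gamma) + list(self.beta)
        return arrays

    def n_parameters(self) -> int:
        """Trainable count from the actual arrays (cross-check for
        :func:`count_parameters`)."""
        return sum(a.size for a in self._trainable_arrays())

    # -- forward / backward ---------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        cfg = self.cfg
        cache = {"a": [X], "z": [], "zhat": [], "mu": [], "ivar": []}
        a = X
        for i in range(cfg.hidden_layers):
            z = a @ self.W[i] + self.b[i]
            if cfg.batch_norm:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.run_mean[i] = _BN_MOMENTUM * self.run_mean[i] + (1 - _BN_MOMENTUM) * mu
                    self.run_var[i] = _BN_MOMENTUM * self.run_var[i] + (1 - _BN_MOMENTUM) * var
                else:
                    mu, var = self.run_mean[i], self.run_var[i]
                ivar = 1.0 / np.sqrt(var + _BN_EPS)
                zhat = (z - mu) * ivar
                h = self.gamma[i] * zhat + self.beta[i]
            else:
                zhat, mu, ivar = z, None, None
                h = z
            a = np.maximum(h, 0.0)
            cache["z"].append(z)
            cache["zhat"].append(zhat)
            cache["mu"].append(mu)
            cache["ivar"].append(ivar)
            cache["a"].append(a)
        logits = a @ self.W[-1] + self.b[-1]
        p = _sigmoid(logits)
        return p, cache

    def _backward(self, p: np.ndarray, Y: np.ndarray, cache) -> list[np.ndarray]:
        cfg = self.cfg
        n, d_out = p.shape
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        grads_g = [None] * cfg.hidden_layers
        grads_be = [None] * cfg.hidden_layers
        dlogits = (p - Y) / (n * d_out)  # mean BCE over batch and outputs
        a_last = cache["a"][-1]
        grads_W[-1] = a_last.T @ dlogits
        grads_b[-1] = dlogits.sum(axis=0)
        da = dlogits @ self.W[-1].T
        for i in range(cfg.hidden_layers - 1, -1, -1):
            a_i = cache["a"][i + 1]
            dh = da * (a_i > 0)
            if cfg.batch_norm:
                zhat, ivar = cache["zhat"][i], cache["ivar"][i]
                z, mu = cache["z"][i], cache["mu"][i]
                grads_g[i] = (dh * zhat).sum(axis=0)
                grads_be[i] = dh.sum(axis=0)
                dzhat = dh * self.gamma[i]
                m = z.shape[0]
                dvar = np.sum(dzhat * (z - mu), axis=0) * (-0.5) * ivar ** 3
                dmu = -np.sum(dzhat, axis=0) * ivar + dvar * np.mean(-2.0 * (z - mu), axis=0)
                dz = dzhat * ivar + dvar * 2.0 * (z - mu) / m + dmu / m
            else:
                dz = dh
            grads_W[i] = cache["a"][i].T @ dz
            grads_b[i] = dz.sum(axis=0)
            if i > 0:
                da = dz @ self.W[i].T
        grads = grads_W + grads_b
        if cfg.batch_norm:
            grads += grads_g + grads_be
        return grads

    def _adam_step(self, grads: list[np.ndarray]) -> None:
        params = self._trainable_arrays()
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
            }
        st = self._adam_state
        st["t"] += 1
        lr, b1, b2, eps = self.cfg.learning_rate, 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, st["m"], st["v"]):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** st["t"])
            vhat = v / (1 - b2 ** st["t"])
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training -------------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray,
            X_val: np.ndarray | None = None,
            Y_val: np.ndarray | None = None) -> TrainingHistory:
        """Train for ``cfg.epochs`` epochs; returns the per-epoch
        history.  Deterministic for a fixed ``cfg.seed``."""
        cfg = self.cfg
        X = np.asarray(X, dtype=np.float64)
        Y = np.asarray(Y, dtype=np.float64)
        if X.shape[1] != cfg.input_dim:
            raise ValueError(
                f"feature dimension {X.shape[1]} != input_dim {cfg.input_dim}")
        history = TrainingHistory()
        n = X.shape[0]
        for _epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                if idx.size < 2 and cfg.batch_norm:
                    continue  # batch statistics undefined for a single sample
                p, cache = self._forward(X[idx], training=True)
                grads = self._backward(p, Y[idx], cache)
                self._adam_step(grads)
            p_tr = self.predict_activations(X)
            history.train_loss.append(_bce(p_tr, Y))
            history.train_accuracy.append(_argmax_accuracy(p_tr, Y))
            if X_val is not None:
                p_va = self.predict_activations(X_val)
                history.val_loss.append(_bce(p_va, Y_val))
                history.val_accuracy.append(_argmax_accuracy(p_va, Y_val))
        return history

    def predict_activations(self, X: np.ndarray, batch_size: int = 8192) -> np.ndarray:
        """Per-output sigmoid activations in [0,1], shape (n, output_dim)."""
        X = np.asarray(X, dtype=np.float64)
        outs = []
        for start in range(0, X.shape[0], batch_size):
            p, _ = self._forward(X[start:start + batch_size], training=False)
            outs.append(p)
        return np.vstack(outs) if outs else np.empty((0, self.cfg.output_dim))

    # -- persistence ----------------------------------------------------------

    def save(self, prefix) -> None:
        """Write ``<prefix>.npz`` (weights + running stats) and a
        ``<prefix>.json`` sidecar with the configuration."""
        arrays = {}
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        for i in range(self.cfg.hidden_layers):
            arrays[f"gamma{i}"] = self.gamma[i]
            arrays[f"beta{i}"] = self.beta[i]
            arrays[f"run_mean{i}"] = self.run_mean[i]
            arrays[f"run_var{i}"] = self.run_var[i]
        np.savez(f"{prefix}.npz", **arrays)
        with open(f"{prefix}.json", "w") as fh:
            json.dump(asdict(self.cfg), fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "InteractionClassifier":
        with open(f"{prefix}.json") as fh:
            cfg = ModelConfig(**json.load(fh))
        model = cls(cfg)
        with np.load(f"{prefix}.npz") as data:
            for i in range(len(model.W)):
                model.W[i] = data[f"W{i}"]
                model.b[i] = data[f"b{i}"]
            for i in range(cfg.hidden_layers):
                model.gamma[i] = data[f"gamma{i}"]
                model.beta[i] = data[f"beta{i}"]
                model.run_mean[i] = data[f"run_mean{i}"]
                model.run_var[i] = data[f"run_var{i}"]
        return model


def _argmax_accuracy(p: np.ndarray, Y: np.ndarray) -> float:
    # np.argmax returns the first maximum, i.e. ties break to the lowest type id
    return float(np.mean(np.argmax(p, axis=1) == np.argmax(Y, axis=1)))


def one_hot(type_ids: Sequence[int], n_types: int = N_TYPES) -> np.ndarray:
    """Targets for training: type ids (1-based) to one-hot rows."""
    ids = np.asarray(type_ids, dtype=int)
    if ids.size and (ids.min() < 1 or ids.max() > n_types):
        raise ValueError("type ids outside 1..n_types")
    Y = np.zeros((ids.size, n_types))
    Y[np.arange(ids.size), ids - 1] = 1.0
    return Y


def train_model(X_train: np.ndarray, y_train: Sequence[int],
                X_val: np.ndarray | None = None,
                y_val: Sequence[int] | None = None,
                cfg: ModelConfig | None = None
                ) -> tuple[InteractionClassifier, TrainingHistory]:
    """Train a classifier on labeled pair features (1-based type ids)."""
    cfg = cfg or ModelConfig()
    model = InteractionClassifier(cfg)
    Y_train = one_hot(y_train, cfg.output_dim)
    Y_val = one_hot(y_val, cfg.output_dim) if y_val is not None else None
    history = model.fit(X_train, Y_train, X_val, Y_val)
    return model, history


def categorical_accuracy(model: InteractionClassifier, X: np.ndarray,
                         y: Sequence[int]) -> float:
    """Fraction of samples whose highest activation is the gold type;
    ties break to the lowest type id."""
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    p = model.predict_activations(X)
    return _argmax_accuracy(p, one_hot(y, model.cfg.output_dim))


def threshold_types(activations: np.ndarray, threshold: float) -> list[tuple[int, float]]:
    """All (type_id, score) with score >= threshold, descending score;
    score ties break to the lowest type id."""
    activations = np.asarray(activations)
    hits = np.flatnonzero(activations >= threshold)
    ranked = sorted(hits, key=lambda i: (-activations[i], i))
    return [(int(i) + 1, float(activations[i])) for i in ranked]


def predict_types(model: InteractionClassifier, feature: np.ndarray,
                  threshold: float) -> list[tuple[int, float]]:
    """Predicted (type_id, score) pairs for one pair feature at the
    given activation threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    acts = model.predict_activations(np.atleast_2d(feature))[0]
    return threshold_types(acts, threshold)
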