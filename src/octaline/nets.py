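"""1-D CNN and fully connected ANN A-line classifiers.

Implemented directly in NumPy with explicit forward/backward passes.  This
keeps the dependency footprint small and gives exact control over the
guided-backpropagation rule used for saliency (see :mod:`octaline.saliency`).

CNN: input 200 -> replicate-pad 5 -> conv(32, len 11, valid) -> maxpool(2,2)
-> conv(64, len 9, valid) -> maxpool(2,2) -> flatten -> dense 100 (ReLU)
-> dense 3 (softmax).  The padding makes the first feature map the same
length as the input A-line.

ANN: 200 -> 100 (ReLU) -> 50 (ReLU) -> 3 (softmax).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.linalg import blas as _blas

__all__ = [
    "NetConfig",
    "TrainedModel",
    "Sequential",
    "build_cnn",
    "build_ann",
    "cnn_layer_lengths",
    "parameter_count",
    "standardize",
    "class_weights",
    "weighted_cross_entropy",
    "softmax",
    "EarlyStopping",
    "train",
    "predict",
]

N_CLASSES = 3
INPUT_LEN = 200
EPS = 1e-12


@dataclass
class NetConfig:
    arch: str = "cnn"  # {"cnn", "ann"}
    pad: int = 5
    conv1_filters: int = 32
    conv1_len: int = 11
    conv2_filters: int = 64
    conv2_len: int = 9
    pool_size: int = 2
    fc_units: int = 100
    hidden1: int = 100
    hidden2: int = 50
    n_classes: int = N_CLASSES
    input_len: int = INPUT_LEN
    standardization: str = "none"  # {"none", "samplewise", "featurewise"}
    lr: float = 1e-4
    max_epochs: int = 100
    patience: int = 5
    min_rel_improvement: float = 1e-4
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ("cnn", "ann"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if self.standardization not in ("none", "samplewise", "featurewise"):
            raise ValueError(f"unknown standardization {self.standardization!r}")
        for name in ("conv1_filters", "conv1_len", "conv2_filters", "conv2_len",
                     "pool_size", "fc_units", "hidden1", "hidden2", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


# ---------------------------------------------------------------------------
# Layers.  Each stores its forward cache and implements backward(grad,
# guided) -> input grad, accumulating parameter gradients in .grads.


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray, guided: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class ReplicatePad1d(Layer):
    """Replicate the first/last sample ``pad`` times along r.

    Convolutional activations use a length-major (L, N, C) layout so that
    conv layers can run as zero-copy GEMMs over contiguous length slices.
    """

    def __init__(self, pad: int) -> None:
        super().__init__()
        self.pad = pad

    def forward(self, x):
        p = self.pad
        left = np.broadcast_to(x[:1], (p,) + x.shape[1:])
        right = np.broadcast_to(x[-1:], (p,) + x.shape[1:])
        return np.concatenate([left, x, right], axis=0)

    def backward(self, g, guided=False):
        p = self.pad
        core = g[p:-p].copy()
        core[0] += g[:p].sum(axis=0)
        core[-1] += g[-p:].sum(axis=0)
        return core


class Conv1d(Layer):
    """Valid cross-correlation on (L, N, C) activations.

    Weights are stored as (out, in, k).  out[l] = sum_t x[l+t] @ W[:, :, t]^T
    runs as k GEMMs over contiguous slices -- no im2col copies.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        limit = np.sqrt(6.0 / (c_in * k + c_out * k))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(c_out, c_in, k)).astype(np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }

    def forward(self, x):
        L, N, C = x.shape
        k, F = self.k, self.c_out
        Lp = L - k + 1
        W = self.params["W"]
        self._x = x
        out = np.zeros((Lp * N, F), dtype=np.float32)
        outT = out.T  # F-contiguous view: BLAS accumulates in place
        for t in range(k):
            xt = x[t : t + Lp].reshape(Lp * N, C)
            # outT += W_t @ xt^T  (xt.T is an F-contiguous view, no copy)
            res = _blas.sgemm(1.0, np.asfortranarray(W[:, :, t]), xt.T, beta=1.0,
                              c=outT, overwrite_c=1)
            assert res is outT or np.shares_memory(res, out)
        out += self.params["b"]
        return out.reshape(Lp, N, F)

    def backward(self, g, guided=False):
        x, W = self._x, self.params["W"]
        L, N, C = x.shape
        k, F = self.k, self.c_out
        Lp = L - k + 1
        g2 = g.reshape(Lp * N, F)
        gW = np.empty_like(W)
        gx = np.zeros((L, N * C), dtype=np.float32)
        for t in range(k):
            xt = x[t : t + Lp].reshape(Lp * N, C)
            gW[:, :, t] = g2.T @ xt
            sub = gx[t : t + Lp].reshape(Lp * N, C)
            # sub^T += W_t^T @ g2^T  (both transposes are F-contiguous views)
            res = _blas.sgemm(1.0, np.asfortranarray(W[:, :, t].T), g2.T, beta=1.0,
                              c=sub.T, overwrite_c=1)
            assert np.shares_memory(res, gx)
        self.grads["W"] = gW
        self.grads["b"] = g2.sum(axis=0)
        return gx.reshape(L, N, C)


class MaxPool1d(Layer):
    """Max pooling with pool size == stride on (L, N, C); ties break to the
    earlier index."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x):
        L = x.shape[0]
        s = self.size
        Lp = L // s
        self._shape = x.shape
        if s == 2:
            a = x[0 : 2 * Lp : 2]
            b = x[1 : 2 * Lp : 2]
            self._take_b = b > a  # strict: ties go to the first element
            return np.where(self._take_b, b, a)
        xr = x[: Lp * s].reshape(Lp, s, *x.shape[1:])
        self._arg = np.argmax(xr, axis=1)
        return np.max(xr, axis=1)

    def backward(self, g, guided=False):
        s = self.size
        Lp = g.shape[0]
        out = np.zeros(self._shape, dtype=g.dtype)
        zero = np.float32(0)
        if s == 2:
            out[0 : 2 * Lp : 2] = np.where(self._take_b, zero, g)
            out[1 : 2 * Lp : 2] = np.where(self._take_b, g, zero)
            return out
        gx = np.zeros((Lp, s) + self._shape[1:], dtype=g.dtype)
        l, n, c = np.indices((Lp,) + self._shape[1:], sparse=True)
        gx[l, self._arg, n, c] = g
        out[: Lp * s] = gx.reshape((Lp * s,) + self._shape[1:])
        return out


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, g, guided=False):
        g = g * self._mask
        if guided:
            g = np.maximum(g, 0)
        return g


class Flatten(Layer):
    """(L, N, C) -> (N, L*C)."""

    def forward(self, x):
        self._shape = x.shape
        L, N, C = x.shape
        return np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(N, L * C)

    def backward(self, g, guided=False):
        L, N, C = self._shape
        return np.ascontiguousarray(g.reshape(N, L, C).transpose(1, 0, 2))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(n_in, n_out)).astype(np.float32),
            "b": np.zeros(n_out, dtype=np.float32),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g, guided=False):
        self.grads["W"] = (self._x.T @ g).astype(np.float32)
        self.grads["b"] = g.sum(axis=0).astype(np.float32)
        return g @ self.params["W"].T


class Sequential:
    """Minimal layer stack producing class logits (softmax applied by the
    loss / predict helpers)."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...]) -> None:
        self.layers = layers
        # (input_len, 1) selects the (L, N, C) conv layout; (input_len,) is flat
        self.input_shape = input_shape

    def _adapt_in(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        if len(self.input_shape) == 2:
            return np.ascontiguousarray(x.T)[:, :, None]
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self._adapt_in(x)
        for layer in self.layers:
            h = layer.forward(h)
        return h

    def backward(self, g_logits: np.ndarray, guided: bool = False) -> np.ndarray:
        g = np.ascontiguousarray(g_logits, dtype=np.float32)
        for layer in reversed(self.layers):
            g = layer.backward(g, guided=guided)
        if len(self.input_shape) == 2:
            return np.ascontiguousarray(g[:, :, 0].T)
        return g

    def parameters(self):
        for layer in self.layers:
            for name, value in layer.params.items():
                yield layer, name, value

    def get_state(self) -> list[dict]:
        return [copy.deepcopy(layer.params) for layer in self.layers]

    def set_state(self, state: list[dict]) -> None:
        for layer, params in zip(self.layers, state):
            layer.params = copy.deepcopy(params)


def cnn_layer_lengths(cfg: NetConfig) -> dict[str, int]:
    """Shape arithmetic along r for the CNN; raises if inconsistent."""
    padded = cfg.input_len + 2 * cfg.pad
    conv1 = padded - cfg.conv1_len + 1
    if conv1 % cfg.pool_size:
        raise ValueError("conv1 output not divisible by pool size")
    pool1 = conv1 // cfg.pool_size
    conv2 = pool1 - cfg.conv2_len + 1
    if conv2 % cfg.pool_size:
        raise ValueError("conv2 output not divisible by pool size")
    pool2 = conv2 // cfg.pool_size
    return {
        "padded": padded,
        "conv1": conv1,
        "pool1": pool1,
        "conv2": conv2,
        "pool2": pool2,
        "flatten": pool2 * cfg.conv2_filters,
    }


def build_cnn(cfg: NetConfig) -> Sequential:
    if cfg.arch != "cnn":
        raise ValueError("config arch must be 'cnn'")
    lengths = cnn_layer_lengths(cfg)
    rng = np.random.default_rng(cfg.seed)
    layers = [
        ReplicatePad1d(cfg.pad),
        Conv1d(1, cfg.conv1_filters, cfg.conv1_len, rng),
        ReLU(),
        MaxPool1d(cfg.pool_size),
        Conv1d(cfg.conv1_filters, cfg.conv2_filters, cfg.conv2_len, rng),
        ReLU(),
        MaxPool1d(cfg.pool_size),
        Flatten(),
        Dense(lengths["flatten"], cfg.fc_units, rng),
        ReLU(),
        Dense(cfg.fc_units, cfg.n_classes, rng),
    ]
    return Sequential(layers, input_shape=(cfg.input_len, 1))


def build_ann(cfg: NetConfig) -> Sequential:
    if cfg.arch != "ann":
        raise ValueError("config arch must be 'ann'")
    rng = np.random.default_rng(cfg.seed)
    layers = [
        Dense(cfg.input_len, cfg.hidden1, rng),
        ReLU(),
        Dense(cfg.hidden1, cfg.hidden2, rng),
        ReLU(),
        Dense(cfg.hidden2, cfg.n_classes, rng),
    ]
    return Sequential(layers, input_shape=(cfg.input_len,))


def build_model(cfg: NetConfig) -> Sequential:
    return build_cnn(cfg) if cfg.arch == "cnn" else build_ann(cfg)


def parameter_count(model: Sequential) -> int:
    return sum(int(np.prod(v.shape)) for _, _, v in model.parameters())


# ---------------------------------------------------------------------------
# Data standardization, class weighting, loss.


def standardize(
    train: np.ndarray, apply_sets: list[np.ndarray], mode: str
) -> tuple[list[np.ndarray], dict]:
    """Standardize ``apply_sets`` using statistics from ``train`` only.

    samplewise: each A-line centred/scaled by its own mean/std.
    featurewise: per-radial-index mean/std from the training set, applied
    unchanged everywhere; zero stds are floored to 1.
    """
    if mode == "none":
        return [np.asarray(s, dtype=np.float32) for s in apply_sets], {}
    if mode == "samplewise":
        out = []
        for s in apply_sets:
            s = np.asarray(s, dtype=np.float64)
            mu = s.mean(axis=1, keepdims=True)
            sd = s.std(axis=1, keepdims=True)
            sd = np.where(sd == 0, 1.0, sd)
            out.append(((s - mu) / sd).astype(np.float32))
        return out, {}
    if mode == "featurewise":
        train = np.asarray(train, dtype=np.float64)
        if train.shape[0] == 0:
            raise ValueError("featurewise standardization needs a non-empty training set")
        mu = train.mean(axis=0)
        sd = train.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        out = [((np.asarray(s, dtype=np.float64) - mu) / sd).astype(np.float32) for s in apply_sets]
        return out, {"mean": mu, "std": sd}
    raise ValueError(f"unknown standardization mode {mode!r}")


def apply_standardization(X: np.ndarray, mode: str, stats: dict) -> np.ndarray:
    if mode == "none":
        return np.asarray(X, dtype=np.float32)
    if mode == "samplewise":
        X = np.asarray(X, dtype=np.float64)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return ((X - mu) / sd).astype(np.float32)
    if mode == "featurewise":
        return ((np.asarray(X, dtype=np.float64) - stats["mean"]) / stats["std"]).astype(np.float32)
    raise ValueError(f"unknown standardization mode {mode!r}")


def class_weights(counts) -> np.ndarray:
    """Inverse-proportion class weights, scaled so the most frequent class
    has weight 1 (the conventional "4, 4, 1"-style pattern)."""
    counts = np.asarray(counts, dtype=float)
    for i, c in enumerate(counts):
        if c <= 0:
            raise ValueError(f"class {CLASS_INDEX_NAMES[i]!r} has zero examples")
    props = counts / counts.sum()
    w = 1.0 / props
    return w / w.min()


CLASS_INDEX_NAMES = ("fibrocalcific", "fibrolipidic", "other")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    y_onehot: np.ndarray, p: np.ndarray, weights=None
) -> float:
    """Mean over examples of w_class * (-log p[true class])."""
    y_onehot = np.asarray(y_onehot, dtype=float)
    p = np.asarray(p, dtype=float)
    if y_onehot.ndim == 1:
        y_onehot = y_onehot[None, :]
        p = p[None, :]
    if weights is None:
        weights = np.ones(p.shape[1])
    weights = np.asarray(weights, dtype=float)
    p_true = np.clip((p * y_onehot).sum(axis=1), EPS, None)
    w = y_onehot @ weights
    return float(np.mean(w * (-np.log(p_true))))


def _loss_and_grad(logits, y_idx, weights):
    """Weighted CE from logits; returns (loss, dL/dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    w = weights[y_idx]
    p_true = np.clip(p[np.arange(n), y_idx], EPS, None)
    loss = float(np.mean(w * (-np.log(p_true))))
    g = p.copy()
    g[np.arange(n), y_idx] -= 1.0
    g *= (w / n)[:, None]
    return loss, g.astype(np.float32)


# ---------------------------------------------------------------------------
# Optimizer and early stopping.


class Adam:
    def __init__(self, model: Sequential, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in layer.params.items()} for layer in model.layers]
        self.v = [{k: np.zeros_like(v) for k, v in layer.params.items()} for layer in model.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, layer in enumerate(self.model.layers):
            for k in layer.params:
                g = layer.grads.get(k)
                if g is None:
                    continue
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / b1t
                vhat = self.v[i][k] / b2t
                layer.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


class EarlyStopping:
    """Stop when the validation loss fails to improve on the running best by
    more than ``min_rel_improvement`` (relative) for ``patience`` consecutive
    epochs."""

    def __init__(self, patience: int = 5, min_rel_improvement: float = 1e-4):
        self.patience = patience
        self.min_rel = min_rel_improvement
        self.best = np.inf
        self.best_epoch = 0
        self.streak = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        """Record an epoch's validation loss; return True to stop."""
        self.epoch += 1
        if loss < self.best:
            improved = (self.best - loss) / self.best > self.min_rel if np.isfinite(self.best) else True
            self.best = loss
            self.best_epoch = self.epoch
        else:
            improved = False
        if improved:
            self.streak = 0
        else:
            self.streak += 1
        return self.streak >= self.patience


@dataclass
class TrainedModel:
    model: Sequential
    config: NetConfig
    stand_stats: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)
    best_epoch: int = 0


def train(
    model: Sequential,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: NetConfig,
    weights: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Adam + weighted cross-entropy with early stopping; returns the
    parameters of the epoch with minimum (weighted) validation loss."""
    [X_train_s, X_val_s], stats = standardize(X_train, [X_train, X_val], cfg.standardization)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if weights is None:
        counts = np.bincount(y_train, minlength=cfg.n_classes)
        weights = class_weights(counts)
    weights = np.asarray(weights, dtype=np.float64)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, cfg.lr)
    stopper = EarlyStopping(cfg.patience, cfg.min_rel_improvement)
    history = {"train_loss": [], "val_loss": []}
    best_state = model.get_state()
    n = X_train_s.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(X_train_s[idx])
            loss, g = _loss_and_grad(logits, y_train[idx], weights)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            model.backward(g)
            opt.step()
            epoch_loss += loss * idx.size
        train_loss = epoch_loss / n
        val_loss = _evaluate_loss(model, X_val_s, y_val, weights, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch}: train {train_loss:.4f} val {val_loss:.4f}")
        prev_best = stopper.best
        stop = stopper.update(val_loss)
        if val_loss < prev_best:
            best_state = model.get_state()
        if stop:
            break
    model.set_state(best_state)
    return TrainedModel(
        model=model,
        config=cfg,
        stand_stats=stats,
        history=history,
        best_epoch=stopper.best_epoch,
    )


def _evaluate_loss(model, X, y, weights, batch_size):
    total, n = 0.0, X.shape[0]
    for start in range(0, n, batch_size):
        logits = model.forward(X[start : start + batch_size])
        loss, _ = _loss_and_grad(logits, y[start : start + batch_size], weights)
        total += loss * min(batch_size, n - start)
    return total / n


def predict(trained: TrainedModel, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Class probabilities, one triple per A-line (softmax of logits)."""
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != trained.config.input_len:
        raise ValueError(f"expected A-lines of length {trained.config.input_len}, got {X.shape[1]}")
    Xs = apply_standardization(X, trained.config.standardization, trained.stand_stats)
    out = np.empty((X.shape[0], trained.config.n_classes), dtype=np.float64)
    for start in range(0, X.shape[0], batch_size):
        logits = trained.model.forward(Xs[start : start + batch_size])
        out[start : start + batch_size] = softmax(logits)
    return out


def config_to_dict(cfg: NetConfig) -> dict:
    return asdict(cfg)
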