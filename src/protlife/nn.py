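"""A small, deterministic neural network implemented on numpy.

The architecture is the fusion classifier used throughout the package:
the residue-level embedding matrix (a single-channel 2-D image of shape
d_local x L_padded) passes through two Conv2D -> ReLU -> AveragePooling ->
Dropout blocks and is flattened; the resulting projection is concatenated
with the processed 1-D feature block and fed through ``n_layers`` fully
connected ReLU/dropout layers into a single sigmoid output (probability
of the long-lived class). Training minimises binary cross-entropy with
Adam and stops early when validation loss fails to improve for
``patience`` consecutive epochs, restoring the best-validation weights.

Everything (weight init, dropout masks, minibatch order) draws from one
seeded generator, so (seed, data, config) fully determine the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class BuildError(ValueError):
    """The configuration cannot produce a valid network shape."""


# --- layers --------------------------------------------------------------


class Conv2D:
    """Valid-padding 2-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.k = k
        self.c_in, self.c_out = c_in, c_out

    @staticmethod
    def out_shape(h: int, w: int, k: int) -> tuple[int, int]:
        if h < k or w < k:
            raise BuildError(f"conv input {h}x{w} smaller than kernel {k}x{k}")
        return h - k + 1, w - k + 1

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = self.out_shape(h, w, self.k)
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, ho * wo, c * self.k * self.k
        )
        self._cols, self._in_shape = cols, (n, c, h, w)
        out = cols @ self.W.T + self.b
        return out.reshape(n, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, ho, wo = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n, ho * wo, self.c_out)
        cols = self._cols
        self.dW = (
            dmat.reshape(-1, self.c_out).T @ cols.reshape(-1, cols.shape[2])
        ).astype(DTYPE)
        self.db = dmat.sum(axis=(0, 1)).astype(DTYPE)
        dcols = dmat @ self.W  # (n, ho*wo, c*k*k)
        _, c, h, w = self._in_shape
        dcols = dcols.reshape(n, ho, wo, c, self.k, self.k)
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class AvgPool2D:
    """Non-overlapping average pooling; trailing rows/cols are cropped."""

    def __init__(self, p: int = 2):
        self.p = p

    @staticmethod
    def out_shape(h: int, w: int, p: int) -> tuple[int, int]:
        ho, wo = h // p, w // p
        if ho < 1 or wo < 1:
            raise BuildError(f"pooling {p}x{p} collapses a {h}x{w} map")
        return ho, wo

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.p
        ho, wo = self.out_shape(h, w, p)
        self._in_shape = x.shape
        return x[:, :, : ho * p, : wo * p].reshape(n, c, ho, p, wo, p).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, ho, wo = dout.shape
        p = self.p
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        up = np.repeat(np.repeat(dout, p, axis=2), p, axis=3) / (p * p)
        dx[:, :, : ho * p, : wo * p] = up
        return dx


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout:
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = (self._x.T @ dout).astype(DTYPE)
        self.db = dout.sum(axis=0).astype(DTYPE)
        return dout @ self.W.T


# --- network -------------------------------------------------------------


def projection_output_dim(
    d_local: int, L_padded: int, kernel_size: int, n_filters: int, pool_size: int = 2
) -> int:
    """Flattened length after two conv/pool blocks — a pure shape function."""
    h, w = d_local, L_padded
    for _ in range(2):
        h, w = Conv2D.out_shape(h, w, kernel_size)
        h, w = AvgPool2D.out_shape(h, w, pool_size)
    return n_filters * h * w


class HalfLifeNet:
    """Conv projection of the residue matrix fused with 1-D features."""

    def __init__(
        self,
        d_local: int,
        L_padded: int,
        feature_dim: int,
        kernel_size: int = 7,
        n_filters: int = 8,
        n_layers: int = 2,
        n_units: int | str = "input_dim",
        dropout: float = 0.2,
        pool_size: int = 2,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.conv_layers: list = []
        c_in = 1
        h, w = d_local, L_padded
        for _ in range(2):
            Conv2D.out_shape(h, w, kernel_size)  # raises BuildError early
            self.conv_layers += [
                Conv2D(c_in, n_filters, kernel_size, rng),
                ReLU(),
                AvgPool2D(pool_size),
                Dropout(dropout, rng),
            ]
            h, w = Conv2D.out_shape(h, w, kernel_size)
            h, w = AvgPool2D.out_shape(h, w, pool_size)
            c_in = n_filters
        self.proj_dim = n_filters * h * w
        self.input_dim = self.proj_dim + feature_dim
        units = self.input_dim if n_units == "input_dim" else int(n_units)
        self.dense_layers: list = []
        n_in = self.input_dim
        for _ in range(n_layers):
            self.dense_layers += [Dense(n_in, units, rng), ReLU(), Dropout(dropout, rng)]
            n_in = units
        self.out_layer = Dense(n_in, 1, rng)
        self.feature_dim = feature_dim

    # -- parameter bookkeeping (for Adam and best-weights restore) --

    def _param_layers(self):
        return [l for l in self.conv_layers + self.dense_layers + [self.out_layer]
                if isinstance(l, (Conv2D, Dense))]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self._param_layers():
            out += [l.W.copy(), l.b.copy()]
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for l in self._param_layers():
            l.W = next(it).copy()
            l.b = next(it).copy()

    # -- forward / backward --

    def forward(self, x_res: np.ndarray, x_feat: np.ndarray, train: bool = False) -> np.ndarray:
        h = x_res.astype(DTYPE, copy=False)
        for layer in self.conv_layers:
            h = layer.forward(h, train)
        n = h.shape[0]
        self._conv_out_shape = h.shape
        h = h.reshape(n, -1)
        z = np.concatenate([h, x_feat.astype(DTYPE, copy=False)], axis=1)
        for layer in self.dense_layers:
            z = layer.forward(z, train)
        return self.out_layer.forward(z, train)[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        d = self.out_layer.backward(dlogit[:, None].astype(DTYPE))
        for layer in reversed(self.dense_layers):
            d = layer.backward(d)
        d_conv = d[:, : self.proj_dim].reshape(self._conv_out_shape)
        for layer in reversed(self.conv_layers):
            d_conv = layer.backward(d_conv)

    def gradients(self) -> list[np.ndarray]:
        out = []
        for l in self._param_layers():
            out += [l.dW, l.db]
        return out

    def apply_step(self, deltas: Sequence[np.ndarray]) -> None:
        it = iter(deltas)
        for l in self._param_layers():
            l.W += next(it)
            l.b += next(it)

    def predict_proba(self, x_res: np.ndarray, x_feat: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for start in range(0, x_res.shape[0], batch_size):
            z = self.forward(
                x_res[start : start + batch_size],
                x_feat[start : start + batch_size],
                train=False,
            )
            probs.append(_sigmoid(z.astype(np.float64)))
        return np.concatenate(probs) if probs else np.empty(0)


# --- loss / optimiser ----------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    z = logits.astype(np.float64)
    return float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))


class Adam:
    def __init__(self, shapes: Sequence[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a, dtype=np.float64) for a in shapes]
        self.v = [np.zeros_like(a, dtype=np.float64) for a in shapes]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> list[np.ndarray]:
        self.t += 1
        deltas = []
        for i, g in enumerate(grads):
            g = g.astype(np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            deltas.append((-self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE))
        return deltas


class EarlyStopper:
    """Stop when the monitored loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record an epoch's validation loss; returns True to stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


@dataclass
class TrainingLog:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stop_epoch: int = 0


def train_network(
    net: HalfLifeNet,
    x_res: np.ndarray,
    x_feat: np.ndarray,
    y: np.ndarray,
    x_res_val: np.ndarray,
    x_feat_val: np.ndarray,
    y_val: np.ndarray,
    learning_rate: float = 1e-3,
    max_epochs: int = 30,
    batch_size: int = 32,
    patience: int = 5,
    sample_weight: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TrainingLog:
    """Adam + BCE minimisation with early stopping on validation loss.

    ``sample_weight`` rescales each training sample's loss contribution
    (e.g. inverse class frequencies); validation loss stays unweighted.
    The best-validation-loss weights are restored before returning.
    """
    if len(y) == 0 or len(y_val) == 0:
        raise ValueError("empty training or validation split")
    rng = rng if rng is not None else net.rng
    y = y.astype(np.float64)
    y_val = y_val.astype(np.float64)
    if sample_weight is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(sample_weight, dtype=np.float64)
        if w.shape != y.shape or np.any(w < 0):
            raise ValueError("sample_weight must be non-negative, one per sample")
        w = w * len(w) / w.sum()  # mean weight 1 keeps lr scale comparable
    opt = Adam(net.get_weights(), lr=learning_rate)
    stopper = EarlyStopper(patience)
    best_weights = net.get_weights()
    log = TrainingLog()
    n = len(y)
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            logits = net.forward(x_res[sel], x_feat[sel], train=True)
            z = logits.astype(np.float64)
            per_sample = np.maximum(z, 0) - z * y[sel] + np.log1p(np.exp(-np.abs(z)))
            loss = float(np.mean(w[sel] * per_sample))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={learning_rate}); aborting"
                )
            losses.append(loss)
            dlogit = w[sel] * (_sigmoid(z) - y[sel]) / len(sel)
            net.backward(dlogit)
            net.apply_step(opt.step(net.gradients()))
        val_logits = []
        for start in range(0, len(y_val), 256):
            val_logits.append(
                net.forward(
                    x_res_val[start : start + 256],
                    x_feat_val[start : start + 256],
                    train=False,
                )
            )
        vloss = bce_with_logits(np.concatenate(val_logits), y_val)
        log.epochs.append(epoch)
        log.train_loss.append(float(np.mean(losses)))
        log.val_loss.append(vloss)
        if vloss < stopper.best:
            best_weights = net.get_weights()
        if stopper.update(epoch, vloss):
            break
    net.set_weights(best_weights)
    log.stop_epoch = stopper.best_epoch
    return log
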