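"""A compact feed-forward / convolutional / recurrent network core in NumPy.

Implements the layer types needed by the classifier benchmarks — dense,
1-D convolution, max pooling, dropout, unidirectional and bidirectional
LSTM — with softmax cross-entropy loss and the Adam optimizer, in plain
NumPy with explicit backpropagation.  It is written for desk-scale
problems (thousands of short windows), is deterministic given a seed, and
its gradients are verified against numerical differentiation in the test
suite.

Array conventions: dense layers take ``(N, F)``; Conv1D/MaxPool take
``(N, C, L)`` (channels first); LSTM layers take ``(N, T, F)`` and return
the last hidden state ``(N, H)`` (concatenated over directions for the
bidirectional variant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Dropout",
    "Flatten",
    "Conv1D",
    "MaxPool1D",
    "GlobalAvgPool1D",
    "TimeFirst",
    "LSTM",
    "BiLSTM",
    "Network",
    "Adam",
    "softmax_cross_entropy",
]


class Layer:
    """Base layer: forward/backward plus flat parameter access."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1, channels-first (N, C, L) -> (N, F, L-K+1)."""

    def __init__(self, n_in: int, n_filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        self.w = _glorot(rng, (n_filters, n_in, kernel), n_in * kernel, n_filters * kernel)
        self.b = np.zeros(n_filters)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        # patches: (N, C, L_out, K)
        patches = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        self._patches = patches
        out = np.einsum("nclk,fck->nfl", patches, self.w) + self.b[None, :, None]
        return out

    def backward(self, dout):
        self.grads[0][...] = np.einsum("nclk,nfl->fck", self._patches, dout)
        self.grads[1][...] = dout.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        l_out = dout.shape[2]
        for kk in range(self.k):
            # contribution of output position l to input position l+kk
            dx[:, :, kk : kk + l_out] += np.einsum("nfl,fc->ncl", dout, self.w[:, :, kk])
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train):
        n, c, l = x.shape
        l_out = l // self.pool
        xr = x[:, :, : l_out * self.pool].reshape(n, c, l_out, self.pool)
        self._argmax = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dout):
        n, c, l_out = dout.shape
        dx = np.zeros((n, c, l_out, self.pool))
        idx = np.indices((n, c, l_out))
        dx[idx[0], idx[1], idx[2], self._argmax] = dout
        full = np.zeros(self._shape)
        full[:, :, : l_out * self.pool] = dx.reshape(n, c, l_out * self.pool)
        return full


class GlobalAvgPool1D(Layer):
    def forward(self, x, train):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._l, axis=2) / self._l


class TimeFirst(Layer):
    """Reorder (N, C, L) channel-first windows into (N, T, F) sequences."""

    def forward(self, x, train):
        return np.transpose(x, (0, 2, 1))

    def backward(self, dout):
        return np.transpose(dout, (0, 2, 1))


class LSTM(Layer):
    """Single-layer LSTM returning the last hidden state.

    Gates are stacked [input, forget, cell, output] in one weight matrix.
    Backward is full BPTT from the last hidden state.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator, reverse: bool = False):
        super().__init__()
        h = n_hidden
        self.h = h
        self.reverse = reverse
        self.wx = _glorot(rng, (n_in, 4 * h), n_in, 4 * h)
        self.wh = _glorot(rng, (h, 4 * h), h, 4 * h)
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def forward(self, x, train):
        if self.reverse:
            x = x[:, ::-1, :]
        n, t, _ = x.shape
        h = self.h
        self._x = x
        hs = np.zeros((t + 1, n, h))
        cs = np.zeros((t + 1, n, h))
        gates = np.zeros((t, n, 4 * h))
        for step in range(t):
            z = x[:, step, :] @ self.wx + hs[step] @ self.wh + self.b
            i = self._sigmoid(z[:, :h])
            f = self._sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = self._sigmoid(z[:, 3 * h :])
            cs[step + 1] = f * cs[step] + i * g
            hs[step + 1] = o * np.tanh(cs[step + 1])
            gates[step] = np.concatenate([i, f, g, o], axis=1)
        self._hs, self._cs, self._gates = hs, cs, gates
        return hs[t]

    def backward(self, dout):
        x, hs, cs, gates = self._x, self._hs, self._cs, self._gates
        n, t, _ = x.shape
        h = self.h
        for g in self.grads:
            g[...] = 0.0
        dh = dout
        dc = np.zeros_like(dout)
        dx = np.zeros_like(x)
        for step in range(t - 1, -1, -1):
            i = gates[step][:, :h]
            f = gates[step][:, h : 2 * h]
            g = gates[step][:, 2 * h : 3 * h]
            o = gates[step][:, 3 * h :]
            tanh_c = np.tanh(cs[step + 1])
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * cs[step]
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            self.grads[0] += x[:, step, :].T @ dz
            self.grads[1] += hs[step].T @ dz
            self.grads[2] += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.wx.T
            dh = dz @ self.wh.T
            dc = dc * f
        if self.reverse:
            dx = dx[:, ::-1, :]
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM: forward and reversed passes, last states concatenated."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(n_in, n_hidden, rng)
        self.bwd = LSTM(n_in, n_hidden, rng, reverse=True)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x, train):
        return np.concatenate([self.fwd.forward(x, train), self.bwd.forward(x, train)], axis=1)

    def backward(self, dout):
        h = self.fwd.h
        return self.fwd.backward(dout[:, :h]) + self.bwd.backward(dout[:, h:])


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(probs[np.arange(n), y] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


@dataclass
class Adam:
    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def init(self, params: Sequence[np.ndarray]) -> None:
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            mh = m / (1 - self.beta1**self.t)
            vh = v / (1 - self.beta2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


class Network:
    """A sequential stack trained with Adam on softmax cross-entropy.

    Training supports mini-batches and early stopping on validation loss.
    """

    def __init__(self, layers: Sequence[Layer], seed: int = 0):
        self.layers = list(layers)
        self.seed = seed
        self.params = [p for lay in self.layers for p in lay.params]
        self.grads = [g for lay in self.layers for g in lay.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [self.forward(x[i : i + batch_size], train=False) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs).argmax(axis=1)

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        total, n = 0.0, 0
        for i in range(0, len(x), batch_size):
            xb, yb = x[i : i + batch_size], y[i : i + batch_size]
            loss, _ = softmax_cross_entropy(self.forward(xb, train=False), yb)
            total += loss * len(yb)
            n += len(yb)
        return total / max(1, n)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        *,
        epochs: int = 50,
        batch_size: int = 32,
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        patience: int = 5,
    ) -> dict:
        opt = Adam(lr=lr, beta1=beta1, beta2=beta2)
        opt.init(self.params)
        rng = np.random.default_rng([self.seed % (2**31), 0xF1])
        best_val = np.inf
        best_params = [p.copy() for p in self.params]
        wait = 0
        history = {"train_loss": [], "val_loss": []}
        for _epoch in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), batch_size):
                idx = order[i : i + batch_size]
                logits = self.forward(x[idx], train=True)
                loss, dout = softmax_cross_entropy(logits, y[idx])
                self.backward(dout)
                opt.step(self.params, self.grads)
                losses.append(loss)
            history["train_loss"].append(float(np.mean(losses)))
            if x_val is not None and len(x_val):
                vl = self.evaluate_loss(x_val, y_val)
                history["val_loss"].append(vl)
                if vl < best_val - 1e-6:
                    best_val = vl
                    best_params = [p.copy() for p in self.params]
                    wait = 0
                else:
                    wait += 1
                    if wait > patience:
                        break
        if x_val is not None and len(x_val):
            for p, bp in zip(self.params, best_params):
                p[...] = bp
        return history
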