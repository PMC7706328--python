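"""Neural-network building blocks on top of :mod:`sdssm.autodiff`.

Dense layers with He initialization, an LSTM cell, batch normalization with
running statistics, inverted dropout, and the Adam optimizer.  Layers expose
their trainable weights through ``params()`` as a flat ``{name: Tensor}``
mapping so models can be checkpointed and optimized uniformly.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Dense", "LSTMCell", "BatchNorm", "Dropout", "Adam",
    "he_init", "clip_gradients", "flatten_params",
]


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """He et al. normal initialization: std = sqrt(2 / fan_in)."""
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=(fan_in, fan_out))


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return np.where(v >= 0, 1.0 / (1.0 + np.exp(-v)),
                    np.exp(np.minimum(v, 0)) / (1.0 + np.exp(np.minimum(v, 0))))


class _SharedBackward:
    """Memoizes a backward intermediate shared by several parent links.

    Within one backward pass every link of a node receives the same output
    gradient object, so identity caching is safe.
    """

    __slots__ = ("fn", "_g", "_out")

    def __init__(self, fn):
        self.fn = fn
        self._g = None
        self._out = None

    def __call__(self, g):
        if self._out is None or self._g is not g:
            self._g = g
            self._out = self.fn(g)
        return self._out


def affine(x, W: Tensor, b: Tensor, activation: str | None = None):
    """Fused ``act(x @ W + b)`` as a single graph node (analytic backward)."""
    xv = ad.value_of(x)
    pre = xv @ W.value + b.value
    if activation == "relu":
        out = np.maximum(pre, 0.0)
    elif activation == "tanh":
        out = np.tanh(pre)
    else:
        out = pre

    def _dpre(g):
        if activation == "relu":
            return g * (pre > 0)
        if activation == "tanh":
            return g * (1.0 - out * out)
        return g

    dpre = _SharedBackward(_dpre)
    links = []
    if isinstance(x, Tensor):
        links.append((x, lambda g: dpre(g) @ W.value.T))
    links.append((W, lambda g: xv.T @ dpre(g)))
    links.append((b, lambda g: dpre(g).sum(axis=0)))
    return Tensor(out, _links=links)


def lstm_step(x, hc_prev, Wx: Tensor, Wh: Tensor, b: Tensor, hidden: int):
    """Fused LSTM step; state is the concatenation [h, c] of size 2*hidden.

    Returns the next [h, c] as one node; the hidden output is a slice of it.
    """
    H = hidden
    xv = ad.value_of(x)
    hcv = ad.value_of(hc_prev)
    h_prev, c_prev = hcv[:, :H], hcv[:, H:]
    gates = xv @ Wx.value + h_prev @ Wh.value + b.value
    i = _sigmoid(gates[:, :H])
    f = _sigmoid(gates[:, H:2 * H])
    g = np.tanh(gates[:, 2 * H:3 * H])
    o = _sigmoid(gates[:, 3 * H:])
    c = f * c_prev + i * g
    th = np.tanh(c)
    out = np.concatenate([o * th, c], axis=1)

    def _dgates(gr):
        dh, dc_direct = gr[:, :H], gr[:, H:]
        dc = dc_direct + dh * o * (1.0 - th * th)
        return np.concatenate([
            dc * g * i * (1.0 - i),
            dc * c_prev * f * (1.0 - f),
            dc * i * (1.0 - g * g),
            dh * th * o * (1.0 - o),
        ], axis=1), dc

    dgates = _SharedBackward(_dgates)

    links = []
    if isinstance(x, Tensor):
        links.append((x, lambda gr: dgates(gr)[0] @ Wx.value.T))
    if isinstance(hc_prev, Tensor):
        def d_hc(gr):
            dgs, dc = dgates(gr)
            return np.concatenate([dgs @ Wh.value.T, dc * f], axis=1)
        links.append((hc_prev, d_hc))
    links.append((Wx, lambda gr: xv.T @ dgates(gr)[0]))
    links.append((Wh, lambda gr: h_prev.T @ dgates(gr)[0]))
    links.append((b, lambda gr: dgates(gr)[0].sum(axis=0)))
    return Tensor(out, _links=links)


class Dense:
    """Affine layer ``x @ W + b`` with optional elementwise activation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str | None = None, w_scale: float = 1.0):
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.W = ad.parameter(w_scale * he_init(rng, in_dim, out_dim))
        self.b = ad.parameter(np.zeros(out_dim))
        if activation not in (None, "relu", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation

    def __call__(self, x):
        return affine(x, self.W, self.b, self.activation)

    def params(self, prefix: str = "") -> dict:
        return {prefix + "W": self.W, prefix + "b": self.b}


class LSTMCell:
    """Standard LSTM cell (input/forget/output gates, forget bias +1)."""

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.in_dim = in_dim
        self.hidden_dim = hidden_dim
        self.Wx = ad.parameter(he_init(rng, in_dim, 4 * hidden_dim))
        self.Wh = ad.parameter(he_init(rng, hidden_dim, 4 * hidden_dim))
        bias = np.zeros(4 * hidden_dim)
        bias[hidden_dim:2 * hidden_dim] = 1.0  # forget-gate bias
        self.b = ad.parameter(bias)

    def init_state(self, batch: int):
        # state is the concatenated [h, c]
        return np.zeros((batch, 2 * self.hidden_dim))

    def __call__(self, x, state):
        H = self.hidden_dim
        hc = lstm_step(x, state, self.Wx, self.Wh, self.b, H)
        h = ad.getitem(hc, (slice(None), slice(0, H)))
        return h, hc

    def params(self, prefix: str = "") -> dict:
        return {prefix + "Wx": self.Wx, prefix + "Wh": self.Wh, prefix + "b": self.b}


class BatchNorm:
    """Per-feature batch normalization with running statistics.

    Training mode normalizes by batch statistics (differentiably) and updates
    the running mean/variance; evaluation mode uses the stored running values.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.dim = dim
        self.momentum = momentum
        self.eps = eps
        self.gamma = ad.parameter(np.ones(dim))
        self.beta = ad.parameter(np.zeros(dim))
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x, train: bool):
        if train:
            mean = ad.mean_(x, axis=0, keepdims=True)
            centered = ad.sub(x, mean)
            var = ad.mean_(ad.square(centered), axis=0, keepdims=True)
            mv, vv = ad.value_of(mean)[0], ad.value_of(var)[0]
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mv
            self.running_var = (1 - m) * self.running_var + m * vv
            norm = ad.div(centered, ad.sqrt(ad.add(var, self.eps)))
        else:
            norm = ad.div(ad.sub(x, self.running_mean),
                          np.sqrt(self.running_var + self.eps))
        return ad.add(ad.mul(norm, self.gamma), self.beta)

    def params(self, prefix: str = "") -> dict:
        return {prefix + "gamma": self.gamma, prefix + "beta": self.beta}


class Dropout:
    """Inverted dropout; identity in evaluation mode or at rate 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def __call__(self, x, train: bool, rng: np.random.Generator | None = None):
        if not train or self.rate == 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(ad.value_of(x).shape) < keep) / keep
        return ad.mul(x, mask)


def flatten_params(params: dict) -> np.ndarray:
    """Concatenate parameter values into one flat vector (sorted by name)."""
    return np.concatenate([params[k].value.ravel() for k in sorted(params)])


def clip_gradients(params: dict, max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float(np.sum(p.grad ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class Adam:
    """Adam optimizer over a ``{name: Tensor}`` parameter mapping."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
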