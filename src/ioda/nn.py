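"""Minimal NumPy neural-network kernels for the sequence classifier.

Only what the model needs is implemented: inference-only 2-D convolution
and max-pooling for the *frozen* feature extractors (no gradients ever
flow into a backbone, so conv backward passes are unnecessary), plus
fully differentiable linear, dropout and LSTM layers and an Adam
optimizer for the trainable upper layers.  Everything is deterministic
given the RNG passed in; no global random state is touched.

Shapes follow the channels-last convention: images are (B, H, W, C),
sequences are (B, L, D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# -- frozen conv kernels ----------------------------------------------------------


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """Cross-correlation of (B,H,W,Cin) with (k,k,Cin,Cout) kernels."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    k = w.shape[0]
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    # win: (B, Ho, Wo, Cin, k, k); contract (Cin, k, k) against w's (2, 0, 1)
    return np.tensordot(win, w, axes=([3, 4, 5], [2, 0, 1])) + b


def maxpool2d(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return win.max(axis=(-2, -1))


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


# -- trainable layers -------------------------------------------------------------


def linear_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    return x @ W + b, x


def linear_backward(dy: np.ndarray, cache: np.ndarray, W: np.ndarray):
    x = cache
    dW = np.tensordot(x, dy, axes=(tuple(range(x.ndim - 1)),) * 2)
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dx = dy @ W.T
    return dx, dW, db


def dropout_forward(x: np.ndarray, p: float, rng: np.random.Generator, training: bool):
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return x, None
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def dropout_backward(dy: np.ndarray, mask) -> np.ndarray:
    return dy if mask is None else dy * mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Stateless single-layer LSTM over (B, L, D) → (B, L, H).

    Hidden and cell states start at zero for every sequence, so no
    information crosses sequence boundaries.  Gate order: input, forget,
    cell candidate, output.
    """
    B, L, _ = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, L, H))
    caches = []
    for t in range(L):
        z = x[:, t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        caches.append((x[:, t], h, c, i, f, g, o, tanh_c))
        h, c = h_new, c_new
        hs[:, t] = h
    return hs, caches


def lstm_backward(dhs: np.ndarray, caches, Wx: np.ndarray, Wh: np.ndarray):
    """Backprop-through-time for :func:`lstm_forward`."""
    B, L, H = dhs.shape
    D = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dx = np.empty((B, L, D))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in reversed(range(L)):
        x_t, h_prev, c_prev, i, f, g, o, tanh_c = caches[t]
        dh = dhs[:, t] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dx, dWx, dWh, db


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# -- optimizer --------------------------------------------------------------------


@dataclass
class Adam:
    """Adam with bias correction; state keyed by parameter name."""

    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: dict = field(default_factory=dict)
    _v: dict = field(default_factory=dict)
    _t: int = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self._t += 1
        t = self._t
        for name, g in grads.items():
            m = self._m.setdefault(name, np.zeros_like(g))
            v = self._v.setdefault(name, np.zeros_like(g))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g**2
            m_hat = m / (1 - self.beta1**t)
            v_hat = v / (1 - self.beta2**t)
            params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# -- frozen backbones -------------------------------------------------------------


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    # float32: backbones are inference-only, and single precision halves cost
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


_TINY_CONV_SEED = 20230505  # fixed: tiny_conv weights are part of the model definition
TINY_CONV_FEATURE_DIM = 64


def tiny_conv_weights() -> dict[str, np.ndarray]:
    """Three frozen He-initialized conv blocks; deterministic by construction."""
    rng = np.random.default_rng(_TINY_CONV_SEED)
    return {
        "w1": _he_init(rng, (8, 8, 3, 16), 8 * 8 * 3),
        "b1": np.zeros(16, dtype=np.float32),
        "w2": _he_init(rng, (4, 4, 16, 32), 4 * 4 * 16),
        "b2": np.zeros(32, dtype=np.float32),
        "w3": _he_init(rng, (3, 3, 32, 64), 3 * 3 * 32),
        "b3": np.zeros(64, dtype=np.float32),
    }


def tiny_conv_forward(x: np.ndarray, weights: dict[str, np.ndarray]) -> np.ndarray:
    """(B, 224, 224, 3) → (B, 64) global-average-pooled features."""
    h = relu(conv2d(x, weights["w1"], weights["b1"], stride=4))  # (B, 55, 55, 16)
    h = relu(conv2d(h, weights["w2"], weights["b2"], stride=4))  # (B, 13, 13, 32)
    h = relu(conv2d(h, weights["w3"], weights["b3"], stride=2))  # (B, 6, 6, 64)
    return h.mean(axis=(1, 2))


ALEXNET_FEATURE_DIM = 256 * 6 * 6


def load_alexnet_weights(path) -> dict[str, np.ndarray]:
    """Load AlexNet feature-layer weights from an .npz archive.

    Expected keys ``conv{1..5}.weight`` (Cout, Cin, k, k — the layout the
    common pretrained checkpoints use) and ``conv{1..5}.bias``; kernels
    are transposed to channels-last on load.
    """
    archive = np.load(path)
    weights = {}
    for i in range(1, 6):
        w = archive[f"conv{i}.weight"]
        weights[f"w{i}"] = np.transpose(w, (2, 3, 1, 0))
        weights[f"b{i}"] = archive[f"conv{i}.bias"]
    return weights


def alexnet_forward(x: np.ndarray, weights: dict[str, np.ndarray]) -> np.ndarray:
    """(B, 224, 224, 3) → (B, 9216) AlexNet 'features' activations."""
    h = relu(conv2d(x, weights["w1"], weights["b1"], stride=4, pad=2))
    h = maxpool2d(h, 3, 2)
    h = relu(conv2d(h, weights["w2"], weights["b2"], pad=2))
    h = maxpool2d(h, 3, 2)
    h = relu(conv2d(h, weights["w3"], weights["b3"], pad=1))
    h = relu(conv2d(h, weights["w4"], weights["b4"], pad=1))
    h = relu(conv2d(h, weights["w5"], weights["b5"], pad=1))
    h = maxpool2d(h, 3, 2)
    return h.reshape(h.shape[0], -1)
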