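"""Minimal NumPy neural-network primitives with explicit backward passes.

Parameters live in a flat ``dict[str, ndarray]``; every forward function
returns its output plus a cache, and the matching backward function
accumulates parameter gradients into a gradient dict and returns the input
gradient.  Everything is float64 and batched over the leading axis, which is
what makes the policy-gradient estimator checkable against finite
differences to tight tolerances.
"""

from __future__ import annotations

import numpy as np

Params = dict[str, np.ndarray]
Grads = dict[str, np.ndarray]


def init_linear(params: Params, name: str, d_in: int, d_out: int,
                rng: np.random.Generator) -> None:
    params[f"{name}.W"] = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)
    params[f"{name}.b"] = np.zeros(d_out)


def linear_forward(params: Params, name: str, x: np.ndarray):
    y = x @ params[f"{name}.W"] + params[f"{name}.b"]
    return y, (name, x)


def linear_backward(params: Params, grads: Grads, cache, dy: np.ndarray):
    name, x = cache
    grads[f"{name}.W"] += x.T @ dy
    grads[f"{name}.b"] += dy.sum(axis=0)
    return dy @ params[f"{name}.W"].T


def init_conv1d(params: Params, name: str, c_in: int, c_out: int, k: int,
                rng: np.random.Generator) -> None:
    fan_in = c_in * k
    params[f"{name}.W"] = rng.standard_normal((c_out, c_in, k)) / np.sqrt(fan_in)
    params[f"{name}.b"] = np.zeros(c_out)


def conv1d_forward(params: Params, name: str, x: np.ndarray):
    """Valid 1-D convolution; x is (B, C_in, L) -> (B, C_out, L-k+1)."""
    W = params[f"{name}.W"]
    c_out, c_in, k = W.shape
    B, _, L = x.shape
    L_out = L - k + 1
    # im2col: (B, C_in*k, L_out)
    cols = np.stack([x[:, :, i:i + L_out] for i in range(k)], axis=2)
    cols = cols.reshape(B, c_in * k, L_out)
    y = np.einsum("of,bfl->bol", W.reshape(c_out, -1), cols)
    y += params[f"{name}.b"][None, :, None]
    return y, (name, cols, x.shape)


def conv1d_backward(params: Params, grads: Grads, cache, dy: np.ndarray):
    name, cols, x_shape = cache
    W = params[f"{name}.W"]
    c_out, c_in, k = W.shape
    B, _, L = x_shape
    L_out = L - k + 1
    grads[f"{name}.W"] += np.einsum("bol,bfl->of", dy, cols).reshape(W.shape)
    grads[f"{name}.b"] += dy.sum(axis=(0, 2))
    dcols = np.einsum("of,bol->bfl", W.reshape(c_out, -1), dy)
    dcols = dcols.reshape(B, c_in, k, L_out)
    dx = np.zeros(x_shape)
    for i in range(k):
        dx[:, :, i:i + L_out] += dcols[:, :, i, :]
    return dx


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(cache, dy: np.ndarray):
    return dy * cache


def tanh_forward(x: np.ndarray):
    y = np.tanh(x)
    return y, y


def tanh_backward(cache, dy: np.ndarray):
    return dy * (1.0 - cache**2)


def dropout_forward(x: np.ndarray, rate: float, rng: np.random.Generator,
                    train: bool):
    if not train or rate <= 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


def dropout_backward(cache, dy: np.ndarray):
    return dy if cache is None else dy * cache


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def init_gru(params: Params, name: str, d_in: int, d_h: int,
             rng: np.random.Generator) -> None:
    for gate in ("z", "r", "n"):
        params[f"{name}.W{gate}"] = (
            rng.standard_normal((d_in, d_h)) / np.sqrt(d_in))
        params[f"{name}.U{gate}"] = (
            rng.standard_normal((d_h, d_h)) / np.sqrt(d_h))
        params[f"{name}.b{gate}"] = np.zeros(d_h)


def gru_forward(params: Params, name: str, x: np.ndarray, h: np.ndarray):
    """One gated-recurrent-unit step.

    z = sig(x Wz + h Uz + bz);  r = sig(x Wr + h Ur + br)
    n = tanh(x Wn + r * (h Un) + bn);  h' = (1 - z) * n + z * h
    """
    p = params
    az = x @ p[f"{name}.Wz"] + h @ p[f"{name}.Uz"] + p[f"{name}.bz"]
    ar = x @ p[f"{name}.Wr"] + h @ p[f"{name}.Ur"] + p[f"{name}.br"]
    z = 1.0 / (1.0 + np.exp(-az))
    r = 1.0 / (1.0 + np.exp(-ar))
    m = h @ p[f"{name}.Un"]
    n = np.tanh(x @ p[f"{name}.Wn"] + r * m + p[f"{name}.bn"])
    h_new = (1.0 - z) * n + z * h
    return h_new, (name, x, h, z, r, m, n)


def gru_backward(params: Params, grads: Grads, cache, dh_new: np.ndarray):
    name, x, h, z, r, m, n = cache
    p = params
    dn = dh_new * (1.0 - z)
    dz = dh_new * (h - n)
    dh = dh_new * z
    dan = dn * (1.0 - n**2)
    dr = dan * m
    dm = dan * r
    daz = dz * z * (1.0 - z)
    dar = dr * r * (1.0 - r)
    grads[f"{name}.Wn"] += x.T @ dan
    grads[f"{name}.bn"] += dan.sum(axis=0)
    grads[f"{name}.Un"] += h.T @ dm
    grads[f"{name}.Wz"] += x.T @ daz
    grads[f"{name}.Uz"] += h.T @ daz
    grads[f"{name}.bz"] += daz.sum(axis=0)
    grads[f"{name}.Wr"] += x.T @ dar
    grads[f"{name}.Ur"] += h.T @ dar
    grads[f"{name}.br"] += dar.sum(axis=0)
    dx = dan @ p[f"{name}.Wn"].T + daz @ p[f"{name}.Wz"].T + dar @ p[f"{name}.Wr"].T
    dh += dm @ p[f"{name}.Un"].T + daz @ p[f"{name}.Uz"].T + dar @ p[f"{name}.Ur"].T
    return dx, dh


def zero_grads(params: Params) -> Grads:
    return {k: np.zeros_like(v) for k, v in params.items()}


class Adam:
    """Standard Adam optimizer over a flat parameter dict."""

    def __init__(self, params: Params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: Params, grads: Grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
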