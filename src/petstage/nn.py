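"""Minimal neural-network primitives (numpy, explicit forward/backward).

Only what the uptake classifier needs: 3x3 same-padding convolution, ReLU,
2x2 max-pooling, dense layers, stable sigmoid/softmax losses and an Adam
optimizer.  All arrays are float32; caches returned by the ``*_forward``
functions are consumed by the matching ``*_backward``.
"""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


# -- convolution (3x3, stride 1, zero padding 1) ------------------------------

def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Nine shifted GEMMs (channels-last) — avoids materializing im2col."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.zeros((n, h + 2, wd + 2, c), dtype=x.dtype)
    xp[:, 1 : h + 1, 1 : wd + 1, :] = x.transpose(0, 2, 3, 1)
    out = np.empty((n, h, wd, f), dtype=np.result_type(x.dtype, w.dtype))
    out[:] = b
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di : di + h, dj : dj + wd, :].reshape(-1, c)
            out += (patch @ w[:, :, di, dj].T).reshape(n, h, wd, f)
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2)), (xp, x.shape)


def conv2d_backward(dout: np.ndarray, cache, w: np.ndarray):
    xp, xshape = cache
    n, c, h, wd = xshape
    f = w.shape[0]
    dflat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, f)
    db = dflat.sum(axis=0)
    dw = np.empty_like(w)
    dxp = np.zeros(xp.shape, dtype=np.result_type(xp.dtype, dout.dtype))
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di : di + h, dj : dj + wd, :].reshape(-1, c)
            dw[:, :, di, dj] = dflat.T @ patch
            dxp[:, di : di + h, dj : dj + wd, :] += (dflat @ w[:, :, di, dj]).reshape(
                n, h, wd, c
            )
    dx = dxp[:, 1 : h + 1, 1 : wd + 1, :].transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx), dw, db


def avgpool2_forward(x: np.ndarray):
    """Fixed 2x2 average pooling (parameter-free front-end reduction)."""
    n, c, h, w = x.shape
    out = x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    return out.astype(x.dtype), (h, w)


def avgpool2_backward(dout: np.ndarray, cache):
    h, w = cache
    g = (dout / 4.0)[:, :, :, None, :, None]
    return np.broadcast_to(
        g, (dout.shape[0], dout.shape[1], h // 2, 2, w // 2, 2)
    ).reshape(dout.shape[0], dout.shape[1], h, w).astype(dout.dtype)


# -- pooling / activations ----------------------------------------------------

def maxpool2_forward(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, xshape = cache
    n, c, h, w = xshape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(n, c, h, w)


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask) -> np.ndarray:
    return dout * mask


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w + b, x


def dense_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray):
    return dout @ w.T, x.T @ dout, dout.sum(axis=0)


# -- output nonlinearities and losses -----------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def bce_loss(p: np.ndarray, y: np.ndarray, z: np.ndarray, pos_weight: float = 1.0):
    """Binary cross-entropy with optional positive-class weight.

    Returns (loss, dloss/dlogit); ``pos_weight`` rescales the loss of
    positive examples to counter class imbalance.
    """
    n = max(1, p.shape[0])
    eps = 1e-12
    w = np.where(y > 0.5, pos_weight, 1.0)
    loss = -np.mean(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return float(loss), (w * (p - y) / n).astype(np.float32)


def masked_ce_loss(probs: np.ndarray, y: np.ndarray):
    """Categorical cross-entropy over rows where ``y >= 0``.

    Rows with ``y < 0`` (no location label) contribute neither loss nor
    gradient; returns (loss, dloss/dlogits).
    """
    mask = y >= 0
    m = max(1, int(mask.sum()))
    eps = 1e-12
    idx = np.where(mask)[0]
    loss = -np.sum(np.log(probs[idx, y[idx]] + eps)) / m
    dlogits = probs.copy()
    dlogits[idx, y[idx]] -= 1.0
    dlogits[~mask] = 0.0
    return float(loss), (dlogits / m).astype(np.float32)


class Adam:
    """Adam optimizer over a named parameter dict (updates in place)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / corr1
            vhat = self.v[k] / corr2
            self.params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                self.params[k].dtype
            )
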