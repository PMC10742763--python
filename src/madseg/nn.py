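"""Minimal numpy neural-network layers with manual backpropagation.

Just enough machinery for the policy/value networks: 3x3 same-padding
convolution (im2col), 2x2 max pooling, dense layers, ReLU, and Adam.
Everything operates on float64 batches and returns explicit gradient
dictionaries, which keeps the PPO updates transparent and exactly
reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def he_conv(rng: np.random.Generator, f: int, c: int, k: int = 3):
    w = rng.normal(0.0, np.sqrt(2.0 / (c * k * k)), size=(f, c, k, k))
    return w, np.zeros(f)


def orthogonal(rng: np.random.Generator, n_out: int, n_in: int,
               gain: float = np.sqrt(2.0)):
    if n_out >= n_in:
        a = rng.normal(size=(n_out, n_in))
        q, r = np.linalg.qr(a)
        q = q * np.sign(np.diag(r))
    else:
        a = rng.normal(size=(n_in, n_out))
        q, r = np.linalg.qr(a)
        q = (q * np.sign(np.diag(r))).T
    return gain * q, np.zeros(n_out)


def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padding 3x3 convolution; x (B,C,H,W) -> (B,F,H,W)."""
    bsz, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))   # (B,C,H,W,3,3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(bsz * h * wd, c * 9)
    out = cols @ w.reshape(f, c * 9).T + b
    out = out.reshape(bsz, h, wd, f).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, w.shape)


def conv3x3_backward(dout: np.ndarray, cache):
    """Gradients (dw, db, dmat); dmat feeds ``conv3x3_input_grad``."""
    cols, x_shape, w_shape = cache
    bsz, c, h, wd = x_shape
    f = w_shape[0]
    dmat = dout.transpose(0, 2, 3, 1).reshape(bsz * h * wd, f)
    dw = (dmat.T @ cols).reshape(w_shape)
    db = dmat.sum(axis=0)
    return dw, db, dmat


def conv3x3_input_grad(dmat: np.ndarray, w: np.ndarray, x_shape):
    """Gradient w.r.t. the convolution input (col2im scatter)."""
    bsz, c, h, wd = x_shape
    f = w.shape[0]
    dcols = dmat @ w.reshape(f, c * 9)                 # (BHW, C*9)
    dcols = dcols.reshape(bsz, h, wd, c, 3, 3)
    dxp = np.zeros((bsz, c, h + 2, wd + 2))
    for i in range(3):
        for j in range(3):
            dxp[:, :, i:i + h, j:j + wd] += \
                dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1]


def maxpool2_forward(x: np.ndarray):
    """2x2/stride-2 max pooling; spatial dims must be even."""
    bsz, f, h, w = x.shape
    xr = x.reshape(bsz, f, h // 2, 2, w // 2, 2) \
          .transpose(0, 1, 2, 4, 3, 5).reshape(bsz, f, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    bsz, f, h, w = x_shape
    dxr = np.zeros((bsz, f, h // 2, w // 2, 4))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(bsz, f, h // 2, w // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(x_shape)
    return dx


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    return x @ w.T + b, x


def dense_backward(dout: np.ndarray, x: np.ndarray, w: np.ndarray):
    dw = dout.T @ x
    db = dout.sum(axis=0)
    dx = dout @ w
    return dw, db, dx


def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0)


def relu_backward(dout: np.ndarray, mask: np.ndarray):
    return dout * mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.clip(z, -30.0, 30.0)
    return 1.0 / (1.0 + np.exp(-z))


class Adam:
    """Adam optimizer over a dictionary of parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
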