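"""Feed-forward layers with explicit backward passes.

All layers operate on numpy arrays with a leading batch axis. Each layer
caches what its backward pass needs during ``forward`` and exposes its
trainable arrays through ``params``/``grads`` (aligned dicts), so an
optimizer can update them in place. Gradients flow all the way back to the
network input, which is what activation maximization needs.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless by default, no trainable parameters."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate is 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv2D(Layer):
    """Stride-1 'same' 2-D convolution over (batch, channels, H, W) inputs.

    Implemented by unrolling kernel offsets into columns (im2col) and a
    single matmul; the backward pass scatters column gradients back with the
    transposed bookkeeping.
    """

    def __init__(self, n_in: int, n_out: int, kernel_size: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel_size
        fan_in = n_in * kh * kw
        fan_out = n_out * kh * kw
        self.W = glorot_uniform(rng, (n_out, n_in, kh, kw), fan_in, fan_out)
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel_size = (kh, kw)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def _im2col(self, xp: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
        n, c = xp.shape[:2]
        kh, kw = self.kernel_size
        cols = np.empty((n, c, kh, kw, out_h, out_w), dtype=xp.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i:i + out_h, j:j + out_w]
        return cols.reshape(n, c * kh * kw, out_h * out_w)

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        kh, kw = self.kernel_size
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        self._cols = self._im2col(xp, h, w)
        self._in_shape = x.shape
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = np.matmul(wmat, self._cols)          # (n, F, h*w)
        out = out.reshape(n, self.W.shape[0], h, w)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        n, c, h, w = self._in_shape
        kh, kw = self.kernel_size
        ph, pw = kh // 2, kw // 2
        f = self.W.shape[0]
        dflat = dout.reshape(n, f, h * w)
        self.db[...] = dflat.sum(axis=(0, 2))
        dwmat = np.tensordot(dflat, self._cols, axes=([0, 2], [0, 2]))
        self.dW[...] = dwmat.reshape(self.W.shape)
        wmat = self.W.reshape(f, -1)
        dcols = np.matmul(wmat.T, dflat)           # (n, K, h*w)
        dcols = dcols.reshape(n, c, kh, kw, h, w)
        dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
        return dxp[:, :, ph:h + ph, pw:w + pw]


class MaxPoolTime(Layer):
    """Max-pooling along the last (time) axis only, pool = stride.

    Frequency resolution is preserved on purpose: the classifier should be
    shift-tolerant in time (bursts drift) but frequency position is the
    discriminative feature. Trailing columns that do not fill a window are
    dropped.
    """

    def __init__(self, pool: int = 2):
        if pool < 1:
            raise ValueError("pool size must be >= 1")
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        p = self.pool
        w_out = w // p
        self._in_shape = x.shape
        if p == 2:                      # fast path: pairwise comparison
            a = x[..., 0:w_out * 2:2]
            b = x[..., 1:w_out * 2:2]
            self._mask = a >= b         # ties route left
            return np.where(self._mask, a, b)
        xr = x[..., :w_out * p].reshape(n, c, h, w_out, p)
        self._argmax = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._in_shape
        p = self.pool
        w_out = w // p
        dx = np.zeros((n, c, h, w))
        if p == 2:
            dx[..., 0:w_out * 2:2] = dout * self._mask
            dx[..., 1:w_out * 2:2] = dout * ~self._mask
            return dx
        dxr = np.zeros((n, c, h, w_out, p))
        np.put_along_axis(dxr, self._argmax[..., None], dout[..., None],
                          axis=-1)
        dx[..., :w_out * p] = dxr.reshape(n, c, h, w_out * p)
        return dx
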