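"""LSTM and GRU sequence layers with backpropagation through time.

A spectrogram frame enters as a sequence of per-epoch feature vectors
(one step per 1-s epoch, features = channels x frequency bins). Layers map
(batch, steps, features) -> (batch, steps, units); a stack feeds each
cell's output sequence to the next and the classifier head reads the final
step of the top cell.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, glorot_uniform


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMLayer(Layer):
    """Single LSTM over a full sequence; gate order (i, f, g, o).

    Forget-gate bias initialized to 1 so memory persists early in training.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx = glorot_uniform(rng, (n_in, 4 * units), n_in, units)
        self.Wh = glorot_uniform(rng, (units, 4 * units), units, units)
        self.b = np.zeros(4 * units)
        self.b[units:2 * units] = 1.0
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def grads(self):
        return {"Wx": self.dWx, "Wh": self.dWh, "b": self.db}

    def forward(self, x, train=False, rng=None):
        n, t, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._x = x
        self._cache = []
        out = np.empty((n, t, u))
        for s in range(t):
            a = x[:, s] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(a[:, :u])
            f = _sigmoid(a[:, u:2 * u])
            g = np.tanh(a[:, 2 * u:3 * u])
            o = _sigmoid(a[:, 3 * u:])
            c_new = f * c + i * g
            hc = np.tanh(c_new)
            h_new = o * hc
            self._cache.append((h, c, i, f, g, o, hc))
            h, c = h_new, c_new
            out[:, s] = h
        return out

    def backward(self, dout):
        x = self._x
        n, t, _ = x.shape
        u = self.units
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x)
        dh = np.zeros((n, u))
        dc = np.zeros((n, u))
        for s in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, hc = self._cache[s]
            dh = dh + dout[:, s]
            do = dh * hc
            dc = dc + dh * o * (1.0 - hc * hc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g * g),
                do * o * (1 - o),
            ], axis=1)
            self.dWx += x[:, s].T @ da
            self.dWh += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, s] = da @ self.Wx.T
            dh = da @ self.Wh.T
            dc = dc * f
        return dx


class GRULayer(Layer):
    """Single GRU over a full sequence; gate order (z, r, n).

    Candidate uses the reset gate inside the hidden matmul term:
    n = tanh(x Wxn + r * (h Whn) + bn).
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx = glorot_uniform(rng, (n_in, 3 * units), n_in, units)
        self.Wh = glorot_uniform(rng, (units, 3 * units), units, units)
        self.b = np.zeros(3 * units)
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def grads(self):
        return {"Wx": self.dWx, "Wh": self.dWh, "b": self.db}

    def forward(self, x, train=False, rng=None):
        n, t, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        self._x = x
        self._cache = []
        out = np.empty((n, t, u))
        for s in range(t):
            xa = x[:, s] @ self.Wx + self.b
            ha = h @ self.Wh
            z = _sigmoid(xa[:, :u] + ha[:, :u])
            r = _sigmoid(xa[:, u:2 * u] + ha[:, u:2 * u])
            hn = ha[:, 2 * u:]
            cand = np.tanh(xa[:, 2 * u:] + r * hn)
            h_new = (1 - z) * cand + z * h
            self._cache.append((h, z, r, hn, cand))
            h = h_new
            out[:, s] = h
        return out

    def backward(self, dout):
        x = self._x
        n, t, _ = x.shape
        u = self.units
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(x)
        dh = np.zeros((n, u))
        for s in range(t - 1, -1, -1):
            h_prev, z, r, hn, cand = self._cache[s]
            dh = dh + dout[:, s]
            dcand = dh * (1 - z)
            dz = dh * (h_prev - cand)
            dh_prev = dh * z
            dan = dcand * (1 - cand * cand)
            dr = dan * hn
            dhn = dan * r
            daz = dz * z * (1 - z)
            dar = dr * r * (1 - r)
            dxa = np.concatenate([daz, dar, dan], axis=1)
            dha = np.concatenate([daz, dar, dhn], axis=1)
            self.dWx += x[:, s].T @ dxa
            self.dWh += h_prev.T @ dha
            self.db += dxa.sum(axis=0)
            dx[:, s] = dxa @ self.Wx.T
            dh = dh_prev + dha @ self.Wh.T
        return dx


class LastStep(Layer):
    """Select the final time step of a sequence output."""

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x[:, -1]

    def backward(self, dout):
        dx = np.zeros(self._shape)
        dx[:, -1] = dout
        return dx


class ToSequence(Layer):
    """Reorder a (batch, channels, freq, time) frame into a
    (batch, time, channels*freq) sequence of per-epoch feature vectors."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        self._shape = x.shape
        return np.transpose(x, (0, 3, 1, 2)).reshape(n, w, c * h)

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.transpose(dout.reshape(n, w, c, h), (0, 2, 3, 1))
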