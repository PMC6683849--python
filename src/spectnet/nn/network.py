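"""Sequential network container, loss, and optimizers.

The container threads forward activations and backward gradients through a
layer list, returning the gradient with respect to the network *input* —
used both for training (discarded) and for activation maximization (kept).
"""

from __future__ import annotations

import numpy as np

from .layers import Layer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels ``y``; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Network:
    """A plain sequential stack of layers producing class logits."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            p, g = layer.params(), layer.grads()
            for name in p:
                out.append((p[name], g[name]))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                state[f"layer{i}.{name}"] = arr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                key = f"layer{i}.{name}"
                if key not in state:
                    raise KeyError(f"missing parameter {key}")
                if state[key].shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {key}: "
                        f"{state[key].shape} vs {arr.shape}")
                arr[...] = state[key]


class SGD:
    def __init__(self, net: Network, learning_rate: float = 1e-2,
                 momentum: float = 0.0):
        self.pairs = net.parameters()
        self.lr = learning_rate
        self.momentum = momentum
        self.vel = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self):
        for (p, g), v in zip(self.pairs, self.vel):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    """Adam: SGD with per-parameter adaptive step sizes."""

    def __init__(self, net: Network, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.pairs = net.parameters()
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (p, g), m, v in zip(self.pairs, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def make_optimizer(net: Network, name: str, learning_rate: float):
    if name == "adam":
        return Adam(net, learning_rate=learning_rate)
    if name == "sgd":
        return SGD(net, learning_rate=learning_rate, momentum=0.9)
    raise ValueError(f"unknown optimizer {name!r}; use 'adam' or 'sgd'")


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


def train_network(net: Network, x: np.ndarray, y: np.ndarray, *,
                  n_steps: int, batch_size: int, learning_rate: float,
                  optimizer: str, rng: np.random.Generator
                  ) -> list[float]:
    """Minibatch stochastic-gradient training; returns the per-step loss log.

    Raises :class:`DivergenceError` as soon as the loss is NaN/inf, with the
    step index in the message.
    """
    opt = make_optimizer(net, optimizer, learning_rate)
    n = x.shape[0]
    losses: list[float] = []
    for step in range(n_steps):
        idx = rng.integers(0, n, size=min(batch_size, n))
        logits = net.forward(x[idx], train=True, rng=rng)
        loss, dlogits = softmax_cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise DivergenceError(
                f"training diverged at step {step}: loss={loss}; "
                "reduce the learning rate")
        losses.append(loss)
        net.backward(dlogits)
        opt.step()
    return losses
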