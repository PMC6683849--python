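"""Frame classifiers as scikit-learn style estimators.

Three architectures share one training/prediction contract over
(n, channels, freq_bins, epochs) frame arrays:

* :class:`DCNNClassifier` — "SpectNet": four hidden layers (two
  convolution + time-only max-pool stages, then two dense layers with
  dropout) and a softmax output. Pooling acts along the time axis only, so
  the network is tolerant to when a burst occurs but not to where it sits
  in frequency.
* :class:`RNNClassifier` — three stacked LSTM or GRU cells of 32 hidden
  units reading the frame as a 20-step sequence of per-epoch spectra, with
  dropout between cells.
* :class:`ShallowClassifier` — a single dense hidden layer over the
  flattened frame, the comparison baseline.

Training minimizes frame-level cross-entropy by minibatch stochastic
gradient descent (Adam by default). Dropout is active only during
training; prediction is deterministic.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .containers import FrameSet

__all__ = ["DCNNClassifier", "RNNClassifier", "ShallowClassifier",
           "build_dcnn", "build_rnn", "build_shallow", "train",
           "predict_frames", "save_model", "load_model"]


def _as_frames_array(X) -> np.ndarray:
    x = X.frames if isinstance(X, FrameSet) else np.asarray(X, dtype=float)
    if x.ndim == 3:            # single frame
        x = x[None]
    if x.ndim != 4:
        raise ValueError(
            "expected frames shaped (n, channels, freq_bins, epochs), got "
            f"shape {x.shape}")
    return x


class _FrameClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery; subclasses define the layer stack."""

    def _build_network(self, input_shape: tuple[int, int, int],
                       n_classes: int, rng: np.random.Generator
                       ) -> nn.Network:
        raise NotImplementedError

    def _fit_arrays(self, X) -> tuple[np.ndarray, np.ndarray | None]:
        if isinstance(X, FrameSet):
            return X.frames, X.label_array()
        return _as_frames_array(X), None

    def fit(self, X, y=None):
        """Train on frames X with integer or string frame labels y.

        X may be a FrameSet (labels taken from it when y is None) or an
        (n, channels, freq_bins, epochs) array.
        """
        x, y_fs = self._fit_arrays(X)
        if y is None:
            if y_fs is None:
                raise ValueError("y is required unless X is a FrameSet")
            y_arr = y_fs
            self.classes_ = np.array(X.class_names, dtype=object)
        else:
            y = np.asarray(y)
            self.classes_, y_arr = np.unique(y, return_inverse=True)
        if x.shape[0] != len(y_arr):
            raise ValueError("X and y lengths differ")
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        if not np.isfinite(x).all():
            raise ValueError("frames contain non-finite values")
        self.input_shape_ = x.shape[1:]
        rng = np.random.default_rng(self.random_state)
        self.network_ = self._build_network(self.input_shape_,
                                            len(self.classes_), rng)
        self.loss_history_ = nn.train_network(
            self.network_, x, y_arr, n_steps=self.n_steps,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            optimizer=self.optimizer, rng=rng)
        self.n_features_in_ = int(np.prod(self.input_shape_))
        return self

    def _check_input(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        x = _as_frames_array(X)
        if x.shape[1:] != self.input_shape_:
            raise ValueError(
                f"frame shape {x.shape[1:]} does not match the fitted "
                f"shape {self.input_shape_}")
        return x

    def decision_function(self, X) -> np.ndarray:
        """Class logits, computed with dropout disabled."""
        x = self._check_input(X)
        out = []
        for i in range(0, x.shape[0], 256):
            out.append(self.network_.forward(x[i:i + 256], train=False))
        return np.concatenate(out, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        return nn.softmax(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def input_gradient(self, x: np.ndarray, target_class: int,
                       kind: str = "logit") -> np.ndarray:
        """Gradient of a class score with respect to the input frame.

        ``kind='logit'`` differentiates the raw output-node activation
        (what activation maximization ascends: it keeps a useful gradient
        even when the softmax saturates); ``kind='logprob'``
        differentiates log p(target_class). Accepts a single frame or a
        batch; returns the same shape.
        """
        check_is_fitted(self, "network_")
        single = np.asarray(x).ndim == 3
        xb = _as_frames_array(x)
        logits = self.network_.forward(xb, train=False)
        if kind == "logit":
            dlogits = np.zeros_like(logits)
            dlogits[:, target_class] = 1.0
        elif kind == "logprob":
            dlogits = -nn.softmax(logits)
            dlogits[:, target_class] += 1.0
        else:
            raise ValueError("kind must be 'logit' or 'logprob'")
        grad = self.network_.backward(dlogits)
        return grad[0] if single else grad

    def n_parameters(self) -> int:
        check_is_fitted(self, "network_")
        return self.network_.n_parameters()


class DCNNClassifier(_FrameClassifier):
    """Convolutional spectrogram-frame classifier ("SpectNet").

    Parameters
    ----------
    conv_filters : tuple of int
        Filters in the two convolution stages.
    kernel_size : tuple of int
        (frequency, time) kernel extent, 'same' padding, stride 1.
    pool_size : int
        Time-axis max-pool width (frequency extent is always 1).
    dense_units : tuple of int
        Widths of the two dense hidden layers.
    dropout_rate : float
        Dropout on the dense hidden layers during training.
    n_steps, batch_size, learning_rate, optimizer
        Minibatch SGD schedule; ``optimizer`` is 'adam' or 'sgd'.
    random_state : int or None
        Seeds initialization, batching and dropout; fixed seed gives
        bit-reproducible training.
    """

    def __init__(self, conv_filters=(8, 16), kernel_size=(3, 3),
                 pool_size=2, dense_units=(64, 32), dropout_rate=0.5,
                 n_steps=5000, batch_size=64, learning_rate=1e-3,
                 optimizer="adam", random_state=None):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_size = pool_size
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.random_state = random_state

    def _build_network(self, input_shape, n_classes, rng):
        n_ch, n_freq, n_time = input_shape
        if len(self.conv_filters) != 2 or len(self.dense_units) != 2:
            raise ValueError(
                "the architecture has two conv and two dense hidden layers")
        layers: list[nn.Layer] = []
        c_in, t = n_ch, n_time
        for f in self.conv_filters:
            layers += [nn.Conv2D(c_in, f, tuple(self.kernel_size), rng),
                       nn.ReLU(), nn.MaxPoolTime(self.pool_size)]
            c_in, t = f, t // self.pool_size
            if t < 1:
                raise ValueError("time axis exhausted by pooling")
        layers.append(nn.Flatten())
        d_in = c_in * n_freq * t
        for u in self.dense_units:
            layers += [nn.Dense(d_in, u, rng), nn.ReLU(),
                       nn.Dropout(self.dropout_rate)]
            d_in = u
        layers.append(nn.Dense(d_in, n_classes, rng))
        return nn.Network(layers)


class RNNClassifier(_FrameClassifier):
    """Stacked-recurrent frame classifier (3 cells x 32 units default).

    The frame is read as a sequence over time epochs; each step's feature
    vector is the flattened (channels x freq_bins) epoch spectrum. The
    class logits are read from the final hidden state of the top cell.
    """

    def __init__(self, cell_type="lstm", n_stacked_cells=3, hidden_units=32,
                 dropout_rate=0.2, n_steps=5000, batch_size=64,
                 learning_rate=1e-3, optimizer="adam", random_state=None):
        self.cell_type = cell_type
        self.n_stacked_cells = n_stacked_cells
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.random_state = random_state

    def _build_network(self, input_shape, n_classes, rng):
        if self.cell_type not in ("lstm", "gru"):
            raise ValueError("cell_type must be 'lstm' or 'gru'")
        if self.n_stacked_cells < 1:
            raise ValueError("need at least one recurrent cell")
        cell_cls = nn.LSTMLayer if self.cell_type == "lstm" else nn.GRULayer
        n_ch, n_freq, _ = input_shape
        layers: list[nn.Layer] = [nn.ToSequence()]
        d_in = n_ch * n_freq
        for k in range(self.n_stacked_cells):
            layers.append(cell_cls(d_in, self.hidden_units, rng))
            if k < self.n_stacked_cells - 1 and self.dropout_rate > 0:
                layers.append(nn.Dropout(self.dropout_rate))
            d_in = self.hidden_units
        layers += [nn.LastStep(),
                   nn.Dropout(self.dropout_rate),
                   nn.Dense(d_in, n_classes, rng)]
        return nn.Network(layers)


class ShallowClassifier(_FrameClassifier):
    """Single-hidden-layer dense baseline over the flattened frame."""

    def __init__(self, hidden_units=64, dropout_rate=0.5, n_steps=5000,
                 batch_size=64, learning_rate=1e-3, optimizer="adam",
                 random_state=None):
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        self.n_steps = n_steps
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.random_state = random_state

    def _build_network(self, input_shape, n_classes, rng):
        d_in = int(np.prod(input_shape))
        return nn.Network([
            nn.Flatten(),
            nn.Dense(d_in, self.hidden_units, rng), nn.ReLU(),
            nn.Dropout(self.dropout_rate),
            nn.Dense(self.hidden_units, n_classes, rng),
        ])


# ---------------------------------------------------------------------------
# functional wrappers and checkpointing
# ---------------------------------------------------------------------------

_ARCH = {"dcnn": DCNNClassifier, "rnn": RNNClassifier,
         "shallow": ShallowClassifier}


def build_dcnn(**config) -> DCNNClassifier:
    return DCNNClassifier(**config)


def build_rnn(**config) -> RNNClassifier:
    return RNNClassifier(**config)


def build_shallow(**config) -> ShallowClassifier:
    return ShallowClassifier(**config)


def train(model: _FrameClassifier, train_frames: FrameSet, **overrides):
    """Fit ``model`` on a (balanced, normalized) FrameSet; ``overrides``
    update schedule parameters (n_steps, learning_rate, ...) first."""
    if overrides:
        model.set_params(**overrides)
    return model.fit(train_frames)


def predict_frames(model: _FrameClassifier, frames) -> np.ndarray:
    """Per-frame class-probability rows for a FrameSet or array."""
    return model.predict_proba(frames)


def save_model(model: _FrameClassifier, path: str | Path) -> None:
    """Checkpoint: HDF5 parameter store + JSON config sidecar."""
    check_is_fitted(model, "network_")
    path = Path(path)
    arch = {v: k for k, v in _ARCH.items()}[type(model)]
    with h5py.File(path, "w") as f:
        f.attrs["architecture"] = arch
        for key, arr in model.network_.state_dict().items():
            f.create_dataset(f"params/{key}", data=arr)
        f.create_dataset("classes",
                         data=np.array([str(c) for c in model.classes_],
                                       dtype=h5py.string_dtype()))
        f.attrs["input_shape"] = model.input_shape_
    sidecar = {"architecture": arch, "params": model.get_params()}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str))


def load_model(path: str | Path) -> _FrameClassifier:
    path = Path(path)
    sidecar = json.loads(
        path.with_suffix(path.suffix + ".json").read_text())
    params = sidecar["params"]
    for key in ("conv_filters", "kernel_size", "dense_units"):
        if key in params and isinstance(params[key], str):
            params[key] = tuple(
                int(v) for v in params[key].strip("()").split(",") if v)
    if params.get("random_state") in ("None", None):
        params["random_state"] = None
    else:
        params["random_state"] = int(params["random_state"])
    for key in ("n_steps", "batch_size", "pool_size", "hidden_units",
                "n_stacked_cells"):
        if key in params:
            params[key] = int(params[key])
    for key in ("learning_rate", "dropout_rate"):
        if key in params:
            params[key] = float(params[key])
    model = _ARCH[sidecar["architecture"]](**params)
    with h5py.File(path, "r") as f:
        classes = np.array([c.decode() if isinstance(c, bytes) else c
                            for c in f["classes"][()]], dtype=object)
        input_shape = tuple(int(v) for v in f.attrs["input_shape"])
        rng = np.random.default_rng(0)
        model.classes_ = classes
        model.input_shape_ = input_shape
        model.network_ = model._build_network(input_shape, len(classes), rng)
        state = {key: f[f"params/{key}"][()] for key in f["params"]}
        model.network_.load_state_dict(state)
        model.loss_history_ = []
        model.n_features_in_ = int(np.prod(input_shape))
    return model
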