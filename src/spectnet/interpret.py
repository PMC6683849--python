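"""Activation maximization ("DeepDream") on trained frame classifiers.

Starting from seeded random noise (or a provided frame), gradient ascent
on a chosen output node's activation synthesizes the spectrogram pattern
the network most associates with that class — for models trained on burst
data, a time-frequency image concentrating energy at the class's
characteristic frequency. Differencing two class prototypes shows where
the classes diverge on the time-frequency plane.

The ascent is regularized the way activation maximization usually needs
to be: the gradient is normalized to unit L2 per step (a trust-region
step rather than a raw magnitude), the image decays slightly toward zero
each step (suppressing directions the classifier does not constrain), and
a light Gaussian blur over the (frequency, time) plane discourages
pixel-level adversarial noise. Unregularized ascent saturates the class
probability with images dominated by noise; these defaults produce stable
prototypes on the synthetic burst task.

The ascent runs in the normalized (z-scored) input space the model was
trained in. In that space the image emphasizes *discriminative* cells —
for overlapping classes these sit on the far flank of the class's burst
band. De-normalizing with the training statistics (``DreamImage
.denormalized``) returns the image to amplitude units, where the dominant
frequency coincides with the class's planted burst frequency; quantitative
readings of burst frequency should use the de-normalized image, as one
would read a displayed spectrogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import NormalizationStats, default_freq_axis

__all__ = ["DreamConfig", "DreamImage", "dream", "class_difference",
           "dominant_frequency"]


@dataclass
class DreamConfig:
    """Settings for one activation-maximization run.

    Parameters
    ----------
    target_class : int
        Output node to maximize.
    n_steps : int
        Ascent iterations; 0 returns the initialization unchanged.
    step_size : float
        Step along the (unit-normalized) gradient, in z-score units.
    init : array or None
        Starting image; None draws seeded standard-normal noise.
    decay : float
        Per-step multiplicative shrinkage of the image toward zero;
        1.0 disables it.
    blur_every, blur_sigma : int, float
        Gaussian blur over (freq, time) every ``blur_every`` steps;
        0 disables it.
    normalize_gradient : bool
        Scale each step's gradient to unit L2 norm.
    seed : int or None
        Seeds the noise initialization.
    """

    target_class: int
    n_steps: int = 500
    step_size: float = 0.2
    init: np.ndarray | None = None
    decay: float = 0.99
    blur_every: int = 1
    blur_sigma: float = 0.5
    normalize_gradient: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if not 0 < self.decay <= 1.0:
            raise ValueError("decay must be in (0, 1]")


@dataclass
class DreamImage:
    """A synthesized class-prototype frame and how it was obtained."""

    values: np.ndarray                 # (channels, freq_bins, epochs)
    freq_axis: np.ndarray
    target_class: int
    achieved_score: float              # class probability of the image
    init_score: float
    score_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("values must be (channels, freq_bins, epochs)")

    def denormalized(self, stats: NormalizationStats) -> np.ndarray:
        """Map the image from z-score space back to amplitude units using
        the training normalization statistics."""
        return (self.values * stats.sd[:, :, None]
                + stats.mean[:, :, None])


def _class_probability(model, x: np.ndarray, target: int) -> float:
    return float(model.predict_proba(x[None])[0, target])


def dream(model, cfg: DreamConfig) -> DreamImage:
    """Gradient-ascend the input toward maximal target-class activation.

    Model parameters stay frozen; only the input moves. The returned image
    is the best-scoring iterate (later iterates win ties), so its class
    probability is never below the initialization's. A dead model (zero
    gradient at the start) returns the initialization with a warning.
    """
    shape = model.input_shape_
    if cfg.init is not None:
        x = np.array(cfg.init, dtype=float)
        if x.shape != shape:
            raise ValueError(
                f"init shape {x.shape} does not match model input {shape}")
    else:
        rng = np.random.default_rng(cfg.seed)
        x = rng.standard_normal(shape)
    n_classes = len(model.classes_)
    if not 0 <= cfg.target_class < n_classes:
        raise ValueError(f"target_class must be in [0, {n_classes})")

    init_score = _class_probability(model, x, cfg.target_class)
    best_x, best_score = x.copy(), init_score
    history = [init_score]
    for step in range(cfg.n_steps):
        grad = model.input_gradient(x, cfg.target_class, kind="logit")
        if step == 0 and not np.any(grad):
            warnings.warn("zero input gradient everywhere; model does not "
                          "react to its input — returning the "
                          "initialization", RuntimeWarning, stacklevel=2)
            break
        if cfg.normalize_gradient:
            norm = np.linalg.norm(grad)
            if norm > 0:
                grad = grad / norm
        x = cfg.decay * x + cfg.step_size * grad
        if cfg.blur_every and (step + 1) % cfg.blur_every == 0:
            x = gaussian_filter(x, sigma=(0, cfg.blur_sigma, cfg.blur_sigma))
        score = _class_probability(model, x, cfg.target_class)
        history.append(score)
        if score >= best_score:
            best_score, best_x = score, x.copy()
    freq_axis = default_freq_axis() if shape[1] == len(default_freq_axis()) \
        else np.linspace(4.0, 44.0, shape[1])
    return DreamImage(values=best_x, freq_axis=freq_axis,
                      target_class=cfg.target_class,
                      achieved_score=best_score, init_score=init_score,
                      score_history=history)


def class_difference(dream_a: DreamImage, dream_b: DreamImage
                     ) -> DreamImage:
    """Element-wise prototype difference a - b (axes must agree)."""
    if dream_a.values.shape != dream_b.values.shape:
        raise ValueError("dream images have different shapes")
    if not np.array_equal(dream_a.freq_axis, dream_b.freq_axis):
        raise ValueError("dream images are on different frequency axes")
    return DreamImage(values=dream_a.values - dream_b.values,
                      freq_axis=dream_a.freq_axis,
                      target_class=dream_a.target_class,
                      achieved_score=dream_a.achieved_score,
                      init_score=dream_a.init_score)


def dominant_frequency(image: DreamImage | np.ndarray,
                       freq_axis: np.ndarray | None = None) -> float:
    """Frequency (Hz) of the bin maximizing the channel- and time-averaged
    image. Exact ties resolve to the lowest frequency (argmax convention).

    For dream images, apply this to the de-normalized image
    (:meth:`DreamImage.denormalized`) when reading off burst frequencies
    in amplitude units.
    """
    if isinstance(image, DreamImage):
        values, axis = image.values, image.freq_axis
    else:
        values = np.asarray(image, dtype=float)
        axis = freq_axis if freq_axis is not None else default_freq_axis()
    if values.ndim == 2:
        values = values[None]
    profile = values.mean(axis=(0, 2))
    return float(axis[int(np.argmax(profile))])
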