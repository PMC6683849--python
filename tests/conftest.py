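import numpy as np
import pytest

import spectnet as sn


@pytest.fixture(scope="session")
def small_frameset() -> sn.FrameSet:
    """Two-class burst frameset small enough for fast training: 4 subjects
    per class, 24 frames each, single channel."""
    return sn.generate_class_frameset(sn.default_recipes(),
                                      n_subjects_per_class=4,
                                      frames_per_subject=24, rng_seed=123)


@pytest.fixture(scope="session")
def normalized_small(small_frameset):
    norm = sn.FrameNormalizer().fit(small_frameset.frames)
    x = norm.transform(small_frameset.frames)
    y = small_frameset.label_array()
    return x, y, small_frameset, norm


@pytest.fixture(scope="session")
def trained_dcnn(normalized_small):
    """A DCNN trained to high accuracy on the small synthetic task."""
    x, y, _, _ = normalized_small
    model = sn.DCNNClassifier(n_steps=400, random_state=0)
    return model.fit(x, y)


def fast_dcnn(seed: int, n_steps: int = 250) -> sn.DCNNClassifier:
    return sn.DCNNClassifier(n_steps=n_steps, random_state=seed)
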