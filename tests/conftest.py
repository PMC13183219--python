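import numpy as np
import pytest

from i2idepth.hod import HoDConfig
from i2idepth.synthetic import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_scene():
    """A miniature sensor geometry so image tests stay fast; same noise and
    jitter structure as the full-size default scene."""
    return SceneConfig(
        width=96, height=80, n_frames=6,
        radii=(12.0, 18.0), amplitude=(20.0, 12.0),
        center_jitter=3.0, phase_jitter=0.05,
    )


@pytest.fixture
def small_hod():
    """32-px target with 8-px cells: 16 cells x 9 bins + 4 = 148 features."""
    return HoDConfig(target_size=32, cell_size=8)


def make_separable_sequences(n_per_class, n_classes, T=5, p=24, seed=0, gap=3.0):
    """Sequences whose class identity is a distinct block of active features,
    the rest zeros — linearly separable and sparse like HoD output."""
    rng = np.random.default_rng(seed)
    block = p // n_classes
    x = np.zeros((n_per_class * n_classes, T, p))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for i, c in enumerate(y):
        sl = slice(c * block, (c + 1) * block)
        x[i, :, sl] = gap + rng.standard_normal((T, block))
    perm = rng.permutation(len(y))
    return x[perm], y[perm]
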