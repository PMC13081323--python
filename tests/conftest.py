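import numpy as np
import pytest

from lungwater import CTVolume, LungMask, PatientAnthro


@pytest.fixture
def anthro():
    """Reference patient: 1.77 m male."""
    return PatientAnthro(height=1.77, sex="male")


def make_volume(hu, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(hu, dtype=float), spacing)


def make_mask(mask, spacing=(1.0, 1.0, 1.0)):
    return LungMask(np.asarray(mask), spacing)


def flat_volume(values, spacing=(1.0, 1.0, 1.0)):
    """A (1, 1, n) volume holding the given HU values, with an all-true mask."""
    vals = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return make_volume(vals, spacing), make_mask(np.ones_like(vals, dtype=bool), spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
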