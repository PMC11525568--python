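import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from relaxkit.data_io import IntensitySeries, ResidueKey
from relaxkit.modelfree import FieldContext


@pytest.fixture
def field600():
    return FieldContext(600.0)


@pytest.fixture
def field850():
    return FieldContext(850.0)


@pytest.fixture
def res():
    return ResidueKey(154, "G")


def make_decay_series(rate: float, residue: ResidueKey, i0: float = 100.0,
                      t=None, noise_sigma: float = 1e-9,
                      noise: float = 0.0, rng=None) -> IntensitySeries:
    """Synthetic monoexponential decay, optionally with Gaussian noise."""
    if t is None:
        t = np.arange(0.0, 0.8, 0.1)
    t = np.asarray(t, dtype=float)
    y = i0 * np.exp(-rate * t)
    if noise > 0:
        y = y + (rng or np.random.default_rng(0)).normal(0.0, noise, len(t))
        noise_sigma = noise
    return IntensitySeries(residue, "delay_s", t, y, noise_sigma)
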