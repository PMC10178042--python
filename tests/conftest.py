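import numpy as np
import pytest

from badgerlm.synthetic import SpectraConfig, generate_spectra


@pytest.fixture
def tiny_config() -> SpectraConfig:
    """Small, fast generator configuration (60 spectra, 50 channels)."""
    return SpectraConfig(n_per_class=12, n_channels=50, noise_sd=0.005, seed=11)


@pytest.fixture
def tiny_spectra(tiny_config):
    return generate_spectra(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


class ForcedRNG:
    """Stub generator whose uniform draws all return a constant."""

    def __init__(self, value: float):
        self.value = value

    def random(self, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@pytest.fixture
def forced_rng():
    return ForcedRNG
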