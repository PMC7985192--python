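import numpy as np
import pytest

from refocus.network import GeneratorConfig, RecurrentGenerator


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained generator for shape/determinism/harness tests."""
    return RecurrentGenerator(GeneratorConfig(n_scales=3, base_channels=4),
                              seed=123)


@pytest.fixture(scope="session")
def trained_desk():
    """Desk-scale generator trained on synthetic beads (shared across the
    suite; the expensive fixture is built once)."""
    from refocus.experiments import train_desk_model
    return train_desk_model(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
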