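import numpy as np
import pytest

from spadspec import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-signal dataset with white band noise: 5 strong bands
    among 60, n=120. Session-scoped; treat as read-only."""
    cfg = SimConfig(
        n_samples=120, n_bands=60, seed=42,
        informative_bands=(5, 15, 25, 40, 50),
        effect_sizes=(-0.01, -0.01, -0.01, 0.01, 0.01),
        noise_sd=0.003, spectral_corr_length=0.0,
    )
    return cfg, generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
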