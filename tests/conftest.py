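import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def planted_zero_noise():
    """Two-class planted-motif fixture with no substitution noise."""
    from sensorscreen.simulate import gen_planted_motif_sequences

    return gen_planted_motif_sequences(
        n_classes=2,
        n_per_class=8,
        length=100,
        motif_length=12,
        mutation_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def gpcr_fixture():
    """Seven-helix receptor mimics, zero noise."""
    from sensorscreen.simulate import gen_gpcr_like

    return gen_gpcr_like(
        n_positives=12, n_negatives=12, length=300, helix_length=15, seed=11
    )
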