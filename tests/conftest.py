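import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expression():
    """A tiny deterministic expression mixture with ground truth."""
    from decomix import simulate_expression

    return simulate_expression(
        k=2,
        n_features=120,
        n_samples=14,
        n_markers_per_component=8,
        noise_sd=0.0,
        seed=7,
        marker_background=0.0,
        n_pure_samples_per_component=1,
    )


@pytest.fixture
def small_methylation():
    from decomix import simulate_methylation

    return simulate_methylation(
        k=2,
        n_features=150,
        n_samples=14,
        n_anchor_cpgs=6,
        noise_sd=0.0,
        seed=11,
        n_pure_samples_per_component=1,
    )
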