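import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def small_collection():
    """Low-noise planted collection shared across module tests."""
    from bgcnet import synthetic_data

    records, truth = synthetic_data.gen_bgc_collection(
        n_families=6,
        members_per_family=4,
        vocab_size=600,
        core_size=15,
        p_drop=0.02,
        p_add=0.02,
        seed=11,
    )
    return records, truth
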