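import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ltrkit import (  # noqa: E402
    SimulationConfig,
    build_synthetic_genome,
    make_reference_element,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=42, genome_length=60_000, gc_content=0.4, tsd_length=5)


@pytest.fixture(scope="session")
def reference():
    return make_reference_element(
        "FAM1", superfamily="Copia", lineage="Ale",
        ltr_length=400, internal_length=1200, seed=3,
    )


@pytest.fixture(scope="session")
def planted_genome(small_config, reference):
    """60 kb genome with 4 planted copies of one family (ages 0-3 Mya)."""
    genome, truths = build_synthetic_genome(
        small_config, [reference], copies_per_family=4,
        ages=[0.0, 1e6, 2e6, 3e6],
    )
    return genome, truths


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
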