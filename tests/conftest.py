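import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled study configuration for fast unit tests."""
    from bsaseq import SimConfig

    return SimConfig(
        n_progeny=60,
        n_background_contigs=150,
        contig_length_range=(150, 600),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    from bsaseq import simulate_cross

    return simulate_cross(small_config)


@pytest.fixture(scope="session")
def table1():
    from bsaseq.fixtures import load_table1

    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
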