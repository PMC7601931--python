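import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def published_tables():
    """The two published CLL case-control genotype tallies with SNP definitions."""
    from cllassoc import datasets as d

    return {
        "rs3803800": (d.RS3803800, d.RS3803800_CASE, d.RS3803800_CTRL),
        "rs4985726": (d.RS4985726, d.RS4985726_CASE, d.RS4985726_CTRL),
    }
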