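import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from arfidelity.amplification_simulator import load_polymerases
from arfidelity.locus_model import load_loci

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def loci():
    return load_loci()


@pytest.fixture(scope="session")
def loci_by_id(loci):
    return {l.locus_id: l for l in loci}


@pytest.fixture(scope="session")
def polymerases():
    return load_polymerases()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
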