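import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lamingate import synthetic
from lamingate.genome import GenomeSpec
from lamingate.shm import ReferenceSequence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref565() -> ReferenceSequence:
    """A 565 bp random amplicon, the V-region stand-in used throughout."""
    return synthetic.generate_reference(565, 0.5, 7)


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return GenomeSpec(("chrA", "chrB"), (120, 80), 10_000)


@pytest.fixture(scope="session")
def fixture_config():
    return synthetic.default_fixture_config(0)


def random_reference(rng: np.random.Generator, length: int) -> ReferenceSequence:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return ReferenceSequence("rnd", seq)
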