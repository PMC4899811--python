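import numpy as np
import pytest

from gme.synthetic_data import SimulationConfig

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_config():
    """A fast pipeline configuration for unit-level end-to-end checks."""
    return SimulationConfig(
        seed=11,
        reference_length=2500,
        n_reference_mst_loci=3,
        n_extra_referential_loci=5,
        n_samples=3,
        depth=30.0,
    )
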