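import numpy as np
import pytest

from ssrforge.ssr_scan import ScanConfig
from ssrforge.synthetic_data import PlantSpec, generate_genome


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_config():
    return ScanConfig()


FIVE_PLANTS = [
    PlantSpec("seq1", 500, "AT", 10),
    PlantSpec("seq1", 2000, "A", 25),
    PlantSpec("seq1", 3500, "AAG", 9),
    PlantSpec("seq1", 5000, "ACGT", 8),
    PlantSpec("seq1", 7000, "AACGT", 7),
]


@pytest.fixture(scope="session")
def planted_genome():
    """10 kb genome with 5 planted SSRs, seed 42 (exact truth known)."""
    genome, truth = generate_genome(1, 10_000, FIVE_PLANTS, seed=42)
    return genome, truth
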