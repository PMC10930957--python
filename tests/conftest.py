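import numpy as np
import pytest

from orispan.circular import (
    CircularInterval,
    CircularSequence,
    GeneModel,
)

MITO_L = 16569
MDL1 = GeneModel("MDL1", CircularInterval(15954, 576, "+"), "lncRNA")
MDL1AS = GeneModel("MDL1AS", CircularInterval(16024, 407, "-"), "lncRNA")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def mito_genome() -> CircularSequence:
    """A random 16,569 bp stand-in for the circular mitogenome."""
    rng = np.random.default_rng(16569)
    return CircularSequence("chrM", random_sequence(MITO_L, rng))


@pytest.fixture(scope="session")
def dloop_genes() -> list[GeneModel]:
    """The two origin-spanning D-loop gene models (published coordinates)."""
    return [MDL1, MDL1AS]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
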