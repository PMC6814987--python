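import numpy as np
import pytest

from mitocomp.seqio import Genome

STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Stop-free coding sequence ending in TAA."""
    return "".join(rng.choice(SENSE_CODONS, n_codons - 1)) + "TAA"


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def make_genome():
    def _make(seed: int, n: int, gid: str = "g") -> Genome:
        r = np.random.default_rng(seed)
        return Genome(id=gid, sequence=random_seq(r, n))

    return _make
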