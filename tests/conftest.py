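import numpy as np
import pytest

from asirna.model import TrainingDataset
from asirna.sequence import GUIDE_LEN
from asirna.synthetic import gen_allele_pair, gen_training_dataset

_BASES = "ACGU"


def random_guide(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=GUIDE_LEN))


@pytest.fixture(scope="session")
def allele_pair():
    """Allele pair with full 18-nt flanks on both sides of the variant."""
    pair, _ = gen_allele_pair(41, seed=11)
    return pair


@pytest.fixture(scope="session")
def allele_fasta():
    _, fasta = gen_allele_pair(41, seed=11)
    return fasta


@pytest.fixture(scope="session")
def small_training_set() -> TrainingDataset:
    """200 guides, 6 genes, dinucleotide effect with noise sd 5."""
    return gen_training_dataset(200, 6, "linear_dinuc", 5.0, seed=5)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
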