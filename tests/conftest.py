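import numpy as np
import pytest

from aspasep.seq_io import ProteinRecord
from aspasep.scales import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


@pytest.fixture
def random_records(rng):
    """25 random unlabeled records of varying length."""
    return [
        ProteinRecord(id=f"r{i:03d}", sequence=random_sequence(rng, int(L)))
        for i, L in enumerate(rng.integers(20, 120, size=25))
    ]


@pytest.fixture
def tiny_two_class(rng):
    """Six labeled records, three per class."""
    a = [
        ProteinRecord(id=f"a{i}", sequence=random_sequence(rng, 40), label="bacterial")
        for i in range(3)
    ]
    b = [
        ProteinRecord(id=f"b{i}", sequence=random_sequence(rng, 60), label="fungal")
        for i in range(3)
    ]
    return a, b
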