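import numpy as np
import pytest

from redyeast.io_formats import SeqRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(np.array(list(alphabet))[rng.integers(0, len(alphabet), n)])


@pytest.fixture
def small_genome(rng):
    return SeqRecord("g1", random_seq(rng, 2000))
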