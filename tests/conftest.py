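import numpy as np
import pytest

from fosmidforge import random_dna
from fosmidforge.assembly import Contig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_vector(rng):
    """A synthetic 1.2 kb cloning-vector stand-in (real backbones are ~8 kb;
    a shorter one keeps small-matrix tests exact and fast)."""
    return random_dna(rng, 1200)


@pytest.fixture
def make_contig():
    def _make(seq, cid="c1", cov=100.0):
        return Contig(cid, seq, cov)

    return _make
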