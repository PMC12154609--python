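import numpy as np
import pytest

from parscope import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_10kb(rng):
    return random_dna(10_000, 0.4, rng)


def make_tandem(unit_seq: str, copies: int) -> str:
    return unit_seq * copies
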