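import random

import numpy as np
import pytest

from panins.io_formats import GenomeSequence
from panins.synthetic_cohort import make_reference, make_repeat_library


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate_seq(rng, seq: str, subs: int = 0, indels: int = 0) -> str:
    out = list(seq)
    for _ in range(subs):
        p = rng.randrange(len(out))
        out[p] = rng.choice([c for c in "ACGT" if c != out[p]])
    for _ in range(indels):
        p = rng.randrange(len(out))
        if rng.random() < 0.5:
            out.insert(p, rng.choice("ACGT"))
        elif len(out) > 1:
            del out[p]
    return "".join(out)


@pytest.fixture
def rng():
    return random.Random(0)


@pytest.fixture(scope="session")
def repeat_library():
    return make_repeat_library(2, seed=7)


@pytest.fixture(scope="session")
def small_reference(repeat_library):
    """Two 200 kb chromosomes at 30% planted-repeat density, with truth."""
    return make_reference(2, 200_000, repeat_library, 0.3, seed=11)


@pytest.fixture
def plain_chromosome(rng):
    """A single repeat-free 50 kb chromosome."""
    return GenomeSequence("chr1", random_seq(rng, 50_000))
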