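import numpy as np
import pytest

from palevol.seqmodel import NucSequence, PairwiseAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[rng.integers(0, 4, size=n)].tobytes().decode()


def mutate(seq: str, rate: float, rng) -> str:
    """Point-mutate a DNA string at the given per-site rate."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in idx:
        alts = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = alts[rng.integers(3)]
    return arr.tobytes().decode()


@pytest.fixture
def pair_factory(rng):
    """Build an ungapped PairwiseAlignment of a sequence and a mutated copy."""

    def build(n: int, rate: float) -> PairwiseAlignment:
        a = random_dna(rng, n)
        b = mutate(a, rate, rng)
        return PairwiseAlignment("a", "b", a, b)

    return build
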