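import numpy as np
import pytest

from cicermark.core_io import RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def repeat_rich_dna(rng, length):
    """Random sequence salted with tandem repeats so SSR tests hit loci."""
    parts = []
    total = 0
    while total < length:
        if rng.random() < 0.4:
            k = int(rng.integers(1, 7))
            motif = random_dna(rng, k)
            units = int(rng.integers(2, 12))
            parts.append(motif * units)
        else:
            parts.append(random_dna(rng, int(rng.integers(5, 30)), "ACGTN"))
        total += len(parts[-1])
    return "".join(parts)[:length]
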