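import numpy as np
import pytest

from salivapred.scales import AA_ALPHABET


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_sequence(rng):
    """Factory for random canonical-alphabet sequences."""

    def _make(length: int) -> str:
        return "".join(rng.choice(list(AA_ALPHABET), size=length))

    return _make


@pytest.fixture
def random_sequences(rng, make_sequence):
    """100 random sequences of lengths 20-120."""
    return [make_sequence(int(rng.integers(20, 121))) for _ in range(100)]
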