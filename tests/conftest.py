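import numpy as np
import pytest

from idrcond import config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length: int) -> str:
    aas = np.array(list(config.AMINO_ACIDS))
    return "".join(rng.choice(aas, size=length))


@pytest.fixture
def random_sequences(rng):
    def make(n: int, length: int) -> list[str]:
        return [random_sequence(rng, length) for _ in range(n)]
    return make
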