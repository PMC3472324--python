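import numpy as np
import pytest

from regulonkit.motif_core import Background


@pytest.fixture
def uniform_bg() -> Background:
    return Background.uniform()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20120702)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def make_dna():
    return random_dna
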