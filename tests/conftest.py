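import numpy as np
import pytest

from heveinscan import GB5


@pytest.fixture
def gb5() -> str:
    return GB5


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
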