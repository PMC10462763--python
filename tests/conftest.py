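import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
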