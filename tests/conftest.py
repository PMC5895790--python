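import numpy as np
import pytest

from satkit.io import ReadRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20180411)


def make_read(seq: str, q: int = 40, read_id: str = "r0") -> ReadRecord:
    return ReadRecord(read_id, seq, chr(q + 33) * len(seq))


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
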