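import numpy as np
import pytest

from kmerq.fastq_io import Read

BASES = "ACGT"


def random_read(rng: np.random.Generator, length: int = 60, rid: str = "read", with_n: bool = False) -> Read:
    seq = "".join(rng.choice(list(BASES), size=length))
    if with_n and length > 4:
        pos = rng.integers(0, length)
        seq = seq[:pos] + "N" + seq[pos + 1 :]
    quals = rng.integers(2, 41, size=length)
    return Read(id=rid, sequence=seq, qualities=quals)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def random_reads(rng):
    return [random_read(rng, length=int(rng.integers(30, 80)), rid=f"r{i:03d}") for i in range(20)]
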