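import numpy as np
import pytest

from ontcorrect.seqio import ClusterInput, Read

BASES = "ACGT"


def random_seq(rng, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


def make_read(read_id: str, seq: str, eps: float = 0.07, cluster_id: str = "c") -> Read:
    return Read(read_id, seq, np.full(len(seq), eps), cluster_id=cluster_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def identical_cluster(rng):
    """Five identical error-free reads (the unanimity fixture)."""
    seq = random_seq(rng, 300)
    return ClusterInput("c", [make_read(f"r{i}", seq) for i in range(5)])
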