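import numpy as np
import pytest

from mitodyn.core_io import GenomeRecord


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng):
    """6 kb linear genome with one planted 80 bp direct repeat pair."""
    rep = random_seq(rng, 80)
    seq = random_seq(rng, 2000) + rep + random_seq(rng, 1500) + rep + random_seq(rng, 1500)
    return {"c1": GenomeRecord("c1", seq, "linear")}, rep
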