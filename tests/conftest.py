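import numpy as np
import pytest

from multiscreen.bayes_association import GenotypeCounts


def make_table(snp_id, n0a, n1a, n2a, n0u, n1u, n2u):
    return GenotypeCounts(snp_id, n0a, n1a, n2a, n0u, n1u, n2u)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tables(rng, n, max_total):
    """Random genotype tables with grand total <= max_total."""
    out = []
    for i in range(n):
        counts = rng.multinomial(int(rng.integers(0, max_total + 1)), np.full(6, 1 / 6))
        out.append(GenotypeCounts(f"r{i}", *map(int, counts)))
    return out
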