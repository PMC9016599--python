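import itertools

import numpy as np
import pytest

from entsat import Alignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_alignment():
    return Alignment.from_sequences(
        [
            ("alpha", "AACCGGTTAC"),
            ("beta", "AACCGGTTAA"),
            ("gamma", "AATCGGTAAC"),
            ("delta", "AATCGATAAC"),
        ]
    )


def iid_alignment(rng, n_taxa, n_sites, p=None):
    """Alignment of iid multinomial columns: the full-saturation null."""
    if p is None:
        p = np.full(4, 0.25)
    states = rng.choice(4, size=(n_taxa, n_sites), p=np.asarray(p))
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    return Alignment(tuple(labels), states.astype(np.uint8))


def brute_force_entropy(n, p):
    """Exhaustive multinomial entropy: enumerate all count vectors."""
    from scipy.stats import multinomial

    p = np.asarray(p, dtype=float)
    h = 0.0
    for c in itertools.product(range(n + 1), repeat=4):
        if sum(c) != n:
            continue
        pr = multinomial.pmf(c, n, p)
        if pr > 0:
            h -= pr * np.log2(pr)
    return h
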