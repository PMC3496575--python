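import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def bh_bruteforce(p, alpha):
    """Independent step-up oracle: scan candidate d from m down to 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    ps = np.sort(p)
    for d in range(m, 0, -1):
        if ps[d - 1] <= d * alpha / m:
            return d, p <= d * alpha / m
    return 0, np.zeros(m, dtype=bool)
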