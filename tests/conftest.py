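import numpy as np
import pytest

from infosoup import build_composition_table

NINE_SURVIVORS = frozenset({1, 2, 3, 4, 5, 8, 10, 12, 15})
SIX_DOOMED = frozenset({6, 7, 9, 11, 13, 14})
FOUR_SET = frozenset({1, 2, 4, 8})

#: 0<->1 alphabet swap permutation of type ids
RELABEL = {1: 8, 8: 1, 2: 4, 4: 2, 3: 12, 12: 3, 5: 10, 10: 5,
           6: 6, 9: 9, 7: 14, 14: 7, 11: 13, 13: 11, 15: 15}


@pytest.fixture(scope="session")
def table():
    return build_composition_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_simplex(rng, support=None):
    f = np.zeros(15)
    idx = np.arange(15) if support is None else np.array(sorted(support)) - 1
    w = rng.random(idx.size) + 1e-3
    f[idx] = w / w.sum()
    return f
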