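import math
from itertools import permutations

import numpy as np
import pytest


def naive_pattern_types(series, D, tau):
    """Independent brute-force ordinal typing used as the oracle.

    Enumerates every window explicitly, builds its rank word with ties
    broken by temporal order, and looks the word up in the reverse-
    lexicographic list of permutations of (1..D).
    """
    series = list(series)
    perms = list(permutations(range(1, D + 1)))[::-1]  # reverse-lex
    types = []
    n = len(series) - (D - 1) * tau
    for k in range(n):
        window = [series[k + j * tau] for j in range(D)]
        order = sorted(range(D), key=lambda j: (window[j], j))
        word = [0] * D
        for rank, j in enumerate(order):
            word[j] = rank + 1
        types.append(perms.index(tuple(word)) + 1)
    return types


def naive_pdf(series, D, tau):
    """Brute-force ordinal PDF from the naive typing."""
    types = naive_pattern_types(series, D, tau)
    L = math.factorial(D)
    counts = [types.count(i + 1) for i in range(L)]
    return np.array(counts, dtype=float) / len(types)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
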