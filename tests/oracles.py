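"""Independent brute-force oracles used by the test suite."""
from __future__ import annotations

import itertools

import numpy as np


def vp_distance_bruteforce(a, b, q: float) -> float:
    """Victor–Purpura distance by exhaustive matching enumeration.

    Considers every injective pairing between subsets of the two trains:
    matched spikes cost ``q * |dt|`` each, unmatched spikes cost 1 each
    (delete or insert). Exact for small trains; independent of the dynamic
    program it cross-checks.
    """
    a = list(a)
    b = list(b)
    n, m = len(a), len(b)
    best = float(n + m)
    for k in range(1, min(n, m) + 1):
        for sub_a in itertools.combinations(a, k):
            for sub_b in itertools.permutations(b, k):
                cost = (n - k) + (m - k) + q * sum(
                    abs(x - y) for x, y in zip(sub_a, sub_b)
                )
                best = min(best, cost)
    return best


def plugin_mi_bits(counts) -> float:
    """Plug-in mutual information of a count table, base 2, by direct loops."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    mi = 0.0
    row = counts.sum(axis=1) / total
    col = counts.sum(axis=0) / total
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            p = counts[i, j] / total
            if p > 0:
                mi += p * np.log2(p / (row[i] * col[j]))
    return mi
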