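"""Independent brute-force oracles used only by the test suite."""

import math
from itertools import combinations


def enumerate_overlap_tail(n_universe: int, k_a: int, k_b: int, overlap: int) -> float:
    """P[|draw ∩ A| >= overlap] by exhaustive enumeration of every k_b-subset.

    A is a fixed k_a-subset of an n_universe-element universe; every
    k_b-subset is equally likely. Feasible for n_universe <= 12.
    """
    universe = range(n_universe)
    a = set(range(k_a))
    hits = total = 0
    for draw in combinations(universe, k_b):
        total += 1
        if len(a.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


def closed_form_overlap_tail(n_universe: int, k_a: int, k_b: int, overlap: int) -> float:
    """Tail sum of C(K,i)C(N-K,n-i)/C(N,n) using exact integer arithmetic."""
    denom = math.comb(n_universe, k_b)
    total = 0
    for i in range(overlap, min(k_a, k_b) + 1):
        total += math.comb(k_a, i) * math.comb(n_universe - k_a, k_b - i)
    return total / denom
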