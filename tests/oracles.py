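"""Exact independent oracles for the two tail statistics.

Both work in exact rational arithmetic (binomial) or by literal enumeration
of urn subsets (hypergeometric), deliberately sharing no code with the
implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb


def binomial_upper_tail(k: int, trials: int, p: Fraction = Fraction(1, 2)) -> Fraction:
    """P(X >= k) for X ~ Binomial(trials, p), exactly."""
    if trials == 0:
        return Fraction(1)
    return sum(
        Fraction(comb(trials, j)) * p**j * (1 - p) ** (trials - j)
        for j in range(k, trials + 1)
    )


def hypergeom_upper_tail_enum(k: int, N: int, m: int, n: int) -> Fraction:
    """P(X >= k) by enumerating every n-subset of an N-item urn with m marked.

    Exponential in N; intended for N <= 12.
    """
    marked = set(range(m))
    hits = 0
    total = 0
    for subset in combinations(range(N), n):
        total += 1
        if sum(1 for x in subset if x in marked) >= k:
            hits += 1
    return Fraction(hits, total)
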