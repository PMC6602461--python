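"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: tails are computed by
exact rational arithmetic or literal enumeration of draws, overlaps by a
naive all-pairs scan.
"""

from __future__ import annotations

from bisect import bisect_left
from fractions import Fraction
from itertools import combinations
from math import comb


def exact_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational closed form."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return Fraction(acc, total)


def enumerate_overlap_counts(N: int, n: int) -> list[list[int]]:
    """Literal enumeration of all C(N, n) draws.

    Returns ``counts[K][k]`` = number of size-n subsets of {0..N-1} sharing
    exactly k elements with {0..K-1}, for every K in 0..N simultaneously
    (the overlap with a prefix of length K is a bisect on the sorted draw).
    """
    counts = [[0] * (n + 1) for _ in range(N + 1)]
    for subset in combinations(range(N), n):
        for K in range(N + 1):
            counts[K][bisect_left(subset, K)] += 1
    return counts


def enumerated_tail(counts_for_K: list[int], N: int, n: int, k: int) -> Fraction:
    """Tail P(X >= k) from an enumerated overlap distribution."""
    return Fraction(sum(counts_for_K[k:]), comb(N, n))


def bruteforce_ordered(N: int, term_positions: set[int], query: tuple[int, ...]):
    """Scan every prefix of an ordered query for one term.

    Returns (min exact tail, set of optimal prefix lengths, smallest one).
    """
    K = len(term_positions)
    best: Fraction | None = None
    optimal: list[int] = []
    k = 0
    for ell, pos in enumerate(query, start=1):
        if pos in term_positions:
            k += 1
        p = exact_tail(N, K, ell, k)
        if best is None or p < best:
            best, optimal = p, [ell]
        elif p == best:
            optimal.append(ell)
    return best, set(optimal), min(optimal)


def naive_interval_overlap(
    queries: list[tuple[str, int, int]],
    genes: list[tuple[str, int, int, str]],
) -> list[set[str]]:
    """All-pairs half-open overlap scan; one hit-set per query interval."""
    out = []
    for qc, qs, qe in queries:
        hits = {ref for gc, gs, ge, ref in genes if gc == qc and gs < qe and ge > qs}
        out.append(hits)
    return out
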