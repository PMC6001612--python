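"""Independent reference implementations used to check the package.

Everything here is deliberately naive (exact rational arithmetic, O(n^2)
double loops, textbook formulas) and shares no code with the package paths
it validates.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, sqrt


def exact_binomial_tail(M: int, j: int, N: int, tail: str = "greater_exclusive") -> Fraction:
    """Exact-rational binomial adjacency tail probability."""
    P = Fraction(M, N) * (2 - Fraction(M, N))
    upto = j if tail == "greater_exclusive" else j - 1
    acc = Fraction(0)
    for k in range(0, upto + 1):
        acc += comb(M, k) * P**k * (1 - P) ** (M - k)
    return 1 - acc


def naive_clustered_count(order: list[tuple[str, str]], members: set[str]) -> int:
    """O(n^2) count of member genes with >= 1 directly adjacent member.

    ``order`` is the full gene order as (chromosome, gene_id) tuples.
    """
    n = len(order)
    clustered = set()
    for i, k in itertools.product(range(n), range(n)):
        if i == k:
            continue
        (ci, gi), (ck, gk) = order[i], order[k]
        if ci == ck and abs(i - k) == 1 and gi in members and gk in members:
            clustered.add(gi)
    return len(clustered)


def naive_pearson(x, y) -> float:
    """Textbook product-moment correlation, written out longhand."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = sqrt(sum((a - mx) ** 2 for a in x)) * sqrt(sum((b - my) ** 2 for b in y))
    return num / den


def naive_offset_similarity(x, y, xo=0.0, yo=0.0) -> float:
    """The offset-anchored similarity computed longhand."""
    n = len(x)
    phix = sqrt(sum((a - xo) ** 2 for a in x) / n)
    phiy = sqrt(sum((b - yo) ** 2 for b in y) / n)
    return sum((a - xo) / phix * ((b - yo) / phiy) for a, b in zip(x, y)) / n


def naive_singleton_score(vectors: dict[str, list[float]], singletons: list[str]) -> float:
    """Mean pairwise similarity over all unordered singleton pairs."""
    scores = [
        naive_offset_similarity(vectors[a], vectors[b])
        for a, b in itertools.combinations(singletons, 2)
    ]
    return sum(scores) / len(scores)
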