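"""Independent brute-force oracles used to check the package's fast paths.

These deliberately use the slowest, most literal formulation of each
definition (explicit position sets, the raw step-up recursion, exact
hypergeometric tail sums over rational binomials) and share no code with
the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Dict, Iterable, List, Sequence, Set, Tuple


def position_index(
    intervals: Dict[str, Iterable[Tuple[str, int, int]]]
) -> Dict[Tuple[str, int], Set[str]]:
    """Literal membership map: (chrom, position) -> ids covering it."""
    out: Dict[Tuple[str, int], Set[str]] = {}
    for oid, ivs in intervals.items():
        for chrom, start, end in ivs:
            for pos in range(start, end + 1):
                out.setdefault((chrom, pos), set()).add(oid)
    return out


def brute_force_overlap(
    span: Tuple[str, int, int], index: Dict[Tuple[str, int], Set[str]]
) -> List[str]:
    """Ids sharing >= 1 genomic position with ``span``, via the index."""
    chrom, start, end = span
    hits: Set[str] = set()
    for pos in range(start, end + 1):
        hits |= index.get((chrom, pos), set())
    return sorted(hits)


def brute_force_bh(p: Sequence[float]) -> List[float]:
    """Step-up BH straight from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = min(1.0, running_min)
    return adjusted


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational sum."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(min(Fraction(1), total))


def welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch test computed from first principles."""
    import math

    from scipy.stats import t as tdist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 1.0 if ma == mb else 0.0
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(2 * tdist.sf(abs(t), df))
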