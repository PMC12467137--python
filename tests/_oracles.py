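"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
enumeration, from-definition formulas) and shares no code path with the
implementations it checks.
"""
from __future__ import annotations

import itertools
import math

from cernet.targets import GAP_EXTEND, GAP_OPEN, pair_score


def count_substring(haystack: str, needle: str) -> int:
    """Occurrences of needle by scanning every substring position."""
    return sum(
        1
        for i in range(len(haystack) - len(needle) + 1)
        if haystack[i : i + len(needle)] == needle
    )


def gap_segment_cost(length: int) -> float:
    if length <= 0:
        return 0.0
    return GAP_OPEN + (length - 1) * GAP_EXTEND


def best_local_duplex_score(mirna: str, window: str) -> float:
    """Exhaustive local alignment score by enumerating pairing sets.

    A local duplex is a monotone set of aligned (miRNA, window) positions
    starting and ending on a pair; between consecutive pairs each side pays
    one affine gap segment for its skipped positions.  The miRNA is threaded
    antiparallel (reversed against the window); pair scores use the same
    constants as the implementation, including seed doubling.
    """
    mr = mirna[::-1]
    m, n = len(mr), len(window)
    best = 0.0
    for k in range(1, min(m, n) + 1):
        for mi in itertools.combinations(range(m), k):
            for wj in itertools.combinations(range(n), k):
                score = 0.0
                for t in range(k):
                    pos = m - mi[t]  # original miRNA position, 1-based
                    score += pair_score(mr[mi[t]], window[wj[t]], pos)
                    if t:
                        score += gap_segment_cost(mi[t] - mi[t - 1] - 1)
                        score += gap_segment_cost(wj[t] - wj[t - 1] - 1)
                if score > best:
                    best = score
    return best


def pearson_from_definition(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def average_ranks(v) -> list[float]:
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_from_definition(x, y) -> float:
    return pearson_from_definition(average_ranks(x), average_ranks(y))


def hypergeom_upper_tail_pmf_sum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by explicit summation of the hypergeometric PMF."""
    total = 0.0
    for i in range(max(k, 0), min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return min(total, 1.0)


def enumerate_triples(circ_mir, mir_mrna, circ_mrna):
    """All (c, m, g) combinations whose three edges exist (cubic scan)."""
    cm = {(a, b) for a, b in circ_mir}
    mg = {(a, b) for a, b in mir_mrna}
    cg = {(a, b) for a, b in circ_mrna}
    circs = {c for c, _ in cm}
    mirs = {m for _, m in cm} | {m for m, _ in mg}
    genes = {g for _, g in mg}
    return sorted(
        (c, m, g)
        for c in circs
        for m in mirs
        for g in genes
        if (c, m) in cm and (m, g) in mg and (c, g) in cg
    )
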