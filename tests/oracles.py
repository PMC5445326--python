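"""Independent oracles used by the tests.

Everything here is deliberately naive — exact big-integer arithmetic and
per-threshold rescans — and shares no code with the implementation paths
it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

from rgnn.model import SSNDocument


def exact_hypergeom_pmf(N: int, M: int, n: int, k: int) -> Fraction:
    """Exact hypergeometric point probability as a rational number."""
    return Fraction(math.comb(M, k) * math.comb(N - M, n - k), math.comb(N, n))


def exact_log10_comb(n: int, k: int) -> float:
    return math.log10(math.comb(n, k))


def brute_force_profile(ssn: SSNDocument, step: int = 1):
    """Recompute (Th, Nn, SE) by filtering the edge list from scratch."""
    scores = list(ssn.edges.values())
    t0 = math.floor(min(scores))
    t_end = math.floor(max(scores)) + 1
    rows = []
    for th in range(t0, t_end + 1, step):
        surviving = [(u, v) for (u, v), s in ssn.edges.items() if s >= th]
        nodes = {n for e in surviving for n in e}
        rows.append((th, len(nodes), len(surviving)))
    return rows


def brute_force_a_th(ssn: SSNDocument, step: int = 1):
    """First grid threshold with a strict Nsv rise, in exact arithmetic."""
    rows = brute_force_profile(ssn, step)
    prev = None
    for th, nn, se in rows:
        nsv = Fraction(se, nn) if nn else None
        if prev is not None and nsv is not None and nsv > prev:
            return th
        if nsv is not None:
            prev = nsv
    return None


def brute_force_s_th(ssn: SSNDocument, step: int = 1):
    """First Th_t with ΔrelNn > ΔrelSE, in exact arithmetic."""
    rows = brute_force_profile(ssn, step)
    nn0, se0 = rows[0][1], rows[0][2]
    for (th, nn, se), (_, nn1, se1) in zip(rows, rows[1:]):
        if Fraction(nn - nn1, nn0) > Fraction(se - se1, se0):
            return th
    return None


def rand_index(labels_a, labels_b) -> float:
    """Pair-counting Rand index of two labelings of the same items."""
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            agree += same_a == same_b
    return agree / (n * (n - 1) / 2)
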