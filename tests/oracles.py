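"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations kept free of the package's own code
paths: direct substring comparison for site scanning, exhaustive
residual-sum-of-squares minimisation for the changepoint, exact
rational-arithmetic enumeration for the hypergeometric tail, and the
textbook Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from fractions import Fraction


def brute_force_scan(sequence: str, motifs) -> list[tuple[int, int, str]]:
    """Check every offset against each motif with the maximal-type rule."""
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    eight = {i for i in range(n - 7) if seq[i : i + 8] == motifs.motif_8mer}
    sites = [(i, i + 8, "8mer") for i in eight]
    m8_hits = set()
    for i in range(n - 6):
        if seq[i : i + 7] == motifs.motif_7mer_m8 and i not in eight:
            sites.append((i, i + 7, "7mer-m8"))
            m8_hits.add(i)
    degenerate = motifs.motif_7mer_A1 == motifs.motif_7mer_m8
    for i in range(n - 6):
        if seq[i : i + 7] != motifs.motif_7mer_A1:
            continue
        if i - 1 in eight:  # trailing seven bases of an 8mer
            continue
        if degenerate and (i in m8_hits or i in eight):
            continue
        sites.append((i, i + 7, "7mer-A1"))
    return sorted(sites)


def exhaustive_breakpoint(
    coverage, minseg: int, transform: str = "log2"
) -> tuple[int, float, list[float]]:
    """Exhaustive two-segment RSS minimisation; smallest-k tie-break.

    Returns (best_k, best_rss, rss_per_candidate).
    """
    if transform == "log2":
        y = [math.log2(c + 1.0) for c in coverage]
    else:
        y = [float(c) for c in coverage]
    n = len(y)
    rss_all = []
    for k in range(minseg, n - minseg + 1):
        left, right = y[:k], y[k:]
        ml = sum(left) / len(left)
        mr = sum(right) / len(right)
        rss = sum((v - ml) ** 2 for v in left) + sum((v - mr) ** 2 for v in right)
        rss_all.append(rss)
    best = min(range(len(rss_all)), key=lambda i: rss_all[i])
    return best + minseg, rss_all[best], rss_all


def hypergeom_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by exact enumeration of overlap counts."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            acc += Fraction(math.comb(K, j) * math.comb(N - K, n - j), total)
    return acc


def bh_by_hand(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up computed directly from the definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p_values[i] * m / rank_from_top)
        q[i] = running
    return q
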