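"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: the Fisher oracle uses
exact rational arithmetic over binomial coefficients, the BH oracle applies
the step-up definition literally, and the clustering oracle re-runs the
published four-constant procedure on dense integer arrays.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided(n11: int, n12: int, n21: int, n22: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    r1 = n11 + n12
    c1 = n11 + n21
    n = n11 + n12 + n21 + n22
    denom = comb(n, c1)
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    p_obs = Fraction(comb(r1, n11) * comb(n - r1, c1 - n11), denom)
    total = Fraction(0)
    for k in range(kmin, kmax + 1):
        pk = Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return float(min(total, Fraction(1)))


def bh_stepup(pvals):
    """Literal Benjamini-Hochberg step-up: adj_i = min_{j>=i} p_(j)*m/j."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    for rank_pos, i in enumerate(indexed):
        best = min(
            pvals[indexed[j]] * m / (j + 1)
            for j in range(rank_pos, m)
        )
        adj[i] = min(1.0, best)
    return adj


def cluster_reference(histogram: dict, half_window: int, dist_thresh: int,
                      peak_thresh: int, sum_thresh: int):
    """Greedy-by-smoothed-count clustering on dense arrays.

    Returns a list of (tag_position, support) in ascending position order.
    """
    if not histogram:
        return []
    lo = min(histogram) - 1
    hi = max(histogram) + 1
    counts = [0] * (hi - lo + 1)
    for p, c in histogram.items():
        counts[p - lo] = c
    tags = []
    while True:
        smoothed = [
            sum(counts[max(0, i - half_window):i + half_window + 1])
            for i in range(len(counts))
        ]
        best = None
        for i in range(len(counts)):
            if counts[i] >= peak_thresh:
                if best is None or smoothed[i] > smoothed[best]:
                    best = i
        if best is None:
            break
        members = [
            (i + lo, counts[i])
            for i in range(max(0, best - dist_thresh),
                           min(len(counts), best + dist_thresh + 1))
            if counts[i] > 0
        ]
        support = sum(c for _, c in members)
        if support >= sum_thresh:
            centroid = sum(p * c for p, c in members) / support
            tag = min(members,
                      key=lambda pc: (abs(pc[0] - centroid), -pc[1], pc[0]))[0]
            tags.append((tag, support))
        for p, _ in members:
            counts[p - lo] = 0
    return sorted(tags)
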