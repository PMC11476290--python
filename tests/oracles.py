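"""Independent oracles used only by the test suite.

Deliberately naive implementations: exact rational-arithmetic binomial
tails and the textbook Benjamini-Hochberg step-up, kept free of any
code path they are used to check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def binomial_upper_tail_exact(k: int, n: int, e: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, e), exact rational arithmetic."""
    if k <= 0:
        return Fraction(1)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * e**i * (1 - e) ** (n - i)
    return total


def binomial_tail_table(n: int, e: Fraction) -> list[Fraction]:
    """tail[k] = P(X >= k) for k in 0..n, via suffix sums of the pmf."""
    pmf = [comb(n, i) * e**i * (1 - e) ** (n - i) for i in range(n + 1)]
    tail = [Fraction(0)] * (n + 2)
    for i in range(n, -1, -1):
        tail[i] = tail[i + 1] + pmf[i]
    return tail[: n + 1]


def bh_stepup(pvalues) -> list[bool]:
    """Textbook BH step-up at level 0.05: find the largest i with
    p_(i) <= i/m * alpha and reject hypotheses 1..i."""
    alpha = 0.05
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if pvalues[idx] <= rank / m * alpha:
            k_star = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_star:
            reject[idx] = True
    return reject


def bh_adjusted(pvalues) -> list[float]:
    """BH-adjusted p-values: q_(i) = min over j>=i of (m/j) p_(j)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvalues[idx] * m / rank)
        adj[idx] = running
    return adj
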