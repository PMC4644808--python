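"""Independent brute-force oracles used by the test suite.

These are deliberately written against the mathematical definitions
(exact rational arithmetic, explicit enumeration), independently of the
library code paths they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


def fisher_twotailed_exact(n11: int, n12: int, n21: int, n22: int) -> Fraction:
    """Two-tailed Fisher p by exhaustive same-margin table enumeration.

    Sums the exact hypergeometric point probabilities of every table with
    the observed margins whose probability is <= that of the observed
    table.  Exact rational arithmetic throughout.
    """
    n = n11 + n12 + n21 + n22
    n_set = n11 + n12
    n_query = n11 + n21

    def prob(k: int) -> Fraction:
        return Fraction(
            comb(n_set, k) * comb(n - n_set, n_query - k), comb(n, n_query)
        )

    k_min = max(0, n_query + n_set - n)
    k_max = min(n_query, n_set)
    p_obs = prob(n11)
    return sum(
        (prob(k) for k in range(k_min, k_max + 1) if prob(k) <= p_obs),
        Fraction(0),
    )


def wilcoxon_twosided_enumeration(x: list[float], y: list[float]) -> float:
    """Exact two-sided rank-sum p by enumerating every rank assignment.

    Midranks are assigned by explicit sorting; the p-value is twice the
    smaller tail of the permutation distribution of the x rank sum,
    capped at 1.
    """
    values = list(x) + list(y)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    w = sum(ranks[: len(x)])
    total = le = ge = 0
    for idx in itertools.combinations(range(len(values)), len(x)):
        s = sum(ranks[i] for i in idx)
        total += 1
        if s <= w + 1e-9:
            le += 1
        if s >= w - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def ranksum_exact_twosided_dp(n: int, m: int, w: int) -> float:
    """Exact two-sided rank-sum p for tie-free data via subset-sum counting.

    Counts size-n subsets of {1..n+m} by sum with dynamic programming and
    doubles the smaller tail (cap 1).  ``w`` is the integer rank sum of x.
    """
    total = n + m
    # dp[k][s] = number of k-subsets of 1..total summing to s
    max_s = sum(range(total - n + 1, total + 1))
    dp = [[0] * (max_s + 1) for _ in range(n + 1)]
    dp[0][0] = 1
    for v in range(1, total + 1):
        for k in range(min(v, n), 0, -1):
            row, prev = dp[k], dp[k - 1]
            for s in range(max_s, v - 1, -1):
                if prev[s - v]:
                    row[s] += prev[s - v]
    counts = dp[n]
    n_total = comb(total, n)
    le = sum(counts[: w + 1])
    ge = sum(counts[w:])
    return min(1.0, 2.0 * min(le, ge) / n_total)


def bh_stepup_flags(ps: list[float], alpha: float) -> list[bool]:
    """Benjamini-Hochberg step-up: reject all p up to the largest rank r
    with p_(r) <= (r/t) alpha.  Independent of any library call."""
    t = len(ps)
    order = sorted(range(t), key=lambda i: ps[i])
    k_star = 0
    for rank, i in enumerate(order, start=1):
        if ps[i] <= rank / t * alpha:
            k_star = rank
    flags = [False] * t
    for rank, i in enumerate(order, start=1):
        if rank <= k_star:
            flags[i] = True
    return flags


def holm_adjusted(ps: list[float]) -> list[float]:
    """Holm step-down adjusted p-values: sorted p_i (t-i+1), running max,
    capped at 1, returned in input order."""
    t = len(ps)
    order = sorted(range(t), key=lambda i: ps[i])
    adj = [0.0] * t
    running = 0.0
    for rank, i in enumerate(order, start=1):
        running = max(running, min(1.0, ps[i] * (t - rank + 1)))
        adj[i] = running
    return adj


def ancestors_bruteforce(
    parents: dict[str, set[str]], term: str
) -> set[str]:
    """Transitive parent closure by plain recursive DFS."""
    out: set[str] = set()

    def visit(t: str) -> None:
        for p in parents.get(t, ()):
            if p not in out:
                out.add(p)
                visit(p)

    visit(term)
    return out


def propagate_bruteforce(
    parents: dict[str, set[str]], direct: dict[str, set[str]]
) -> dict[str, set[str]]:
    """Per-gene ancestor-closure propagation, term by term."""
    prop: dict[str, set[str]] = {}
    for term, genes in direct.items():
        for target in {term} | ancestors_bruteforce(parents, term):
            prop.setdefault(target, set()).update(genes)
    return prop
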