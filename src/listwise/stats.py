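"""Hypothesis tests and multiple-testing corrections for enrichment analysis.

Three tests, selected by data type:

* binary (categorical) features -- two-tailed Fisher's exact test on the
  2x2 table of query membership vs. set membership within the background;
* metric features -- two-sided Wilcoxon rank-sum test comparing the values
  of the query genes against the values of the remaining background genes;
* pairwise features (interaction networks) -- a permutation test on the
  number of interactions internal to the query list.

The two-tailed Fisher p-value follows the classical convention: the sum of
the hypergeometric point probabilities of all tables sharing the observed
margins whose probability does not exceed that of the observed table.

The Wilcoxon test uses exact enumeration of the rank-sum distribution
(midranks for ties) while the number of assignments C(n+m, n) is at most
``EXACT_LIMIT``; beyond that a normal approximation with a +/-0.5 continuity
correction and tie-corrected variance is used.

Multiple-testing corrections (Bonferroni, Holm step-down, Benjamini-Hochberg
step-up) are delegated to statsmodels; ``t``, the total number of tests, is
always the number of p-values submitted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom, norm, rankdata
from statsmodels.stats.multitest import multipletests

from .core import Background, InteractionNetwork

#: Switch-over point between the exact and the normal-approximation
#: Wilcoxon path, in number of rank assignments C(n+m, n).  A warning is
#: attached at and above this count.
EXACT_LIMIT = 2500

#: Query sizes below this attract a small-list warning.
SMALL_LIST = 10

#: p-values at or above this attract a "clearly non-significant" warning.
HIGH_P_WARN = 0.25


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 gene counts within background B for query A and gene set G.

    Cells: ``n11`` = |A n G|, ``n12`` = |G \\ A|, ``n21`` = |A \\ G|,
    ``n22`` = |B \\ (A u G)|.  Cells sum to |B|.
    """

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def n_query(self) -> int:
        return self.n11 + self.n21

    @property
    def n_set(self) -> int:
        return self.n11 + self.n12

    @property
    def expected(self) -> float:
        """Expected |A n G| under independence: |A| |G| / |B|."""
        return self.n_query * self.n_set / self.n_total


@dataclass
class TestResult:
    raw_p: float | None
    statistic: float | None
    method: str
    direction: str | None = None
    warnings: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)


def contingency(
    A: Iterable[str], G: Iterable[str], B: Background | Iterable[str]
) -> ContingencyTable:
    """Build the 2x2 table for query A vs. gene set G within background B.

    G is intersected with B before counting; A must be a subset of B.
    """
    bset = B.genes if isinstance(B, Background) else frozenset(B)
    if not bset:
        raise ValueError("empty background")
    aset = frozenset(A)
    if not aset <= bset:
        raise ValueError("query list must be a subset of the background")
    gset = frozenset(G) & bset
    n11 = len(aset & gset)
    n12 = len(gset) - n11
    n21 = len(aset) - n11
    n22 = len(bset) - len(aset) - n12
    return ContingencyTable(n11, n12, n21, n22)


@lru_cache(maxsize=262144)
def _fisher_p_by_overlap(
    n_total: int, n_query: int, n_set: int
) -> tuple[int, tuple[float, ...]]:
    """Two-tailed Fisher p for every possible overlap, given fixed margins.

    Returns ``(k_min, p_values)`` where ``p_values[k - k_min]`` is the
    two-tailed p when the observed overlap is ``k``.  Cached because an
    enrichment run evaluates many features that share |B|, |A| and often
    |G n B|.
    """
    k_min = max(0, n_query + n_set - n_total)
    k_max = min(n_query, n_set)
    k = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(k, n_total, n_set, n_query)
    # relative slack absorbs float noise when distinct tables have exactly
    # equal point probabilities (symmetric margins)
    thresh = pmf * (1.0 + 1e-9)
    ps = np.array([pmf[pmf <= t].sum() for t in thresh])
    return k_min, tuple(np.minimum(ps, 1.0))


def fisher_twotailed(tbl: ContingencyTable) -> TestResult:
    """Two-tailed Fisher's exact test on a contingency table.

    Degenerate margins (an empty row or column) cannot deviate from
    expectation: p = 1 with a warning.  Direction is "over" when the
    observed overlap exceeds its expectation, else "under".
    """
    warnings: list[str] = []
    n = tbl.n_total
    if n == 0:
        raise ValueError("empty contingency table")
    degenerate = (
        tbl.n11 + tbl.n12 == 0
        or tbl.n21 + tbl.n22 == 0
        or tbl.n11 + tbl.n21 == 0
        or tbl.n12 + tbl.n22 == 0
    )
    if degenerate:
        p = 1.0
        warnings.append("degenerate margins")
    else:
        k_min, ps = _fisher_p_by_overlap(n, tbl.n_query, tbl.n_set)
        p = ps[tbl.n11 - k_min]
    direction = "over" if tbl.n11 > tbl.expected else "under"
    if tbl.n12 * tbl.n21 > 0:
        odds = (tbl.n11 * tbl.n22) / (tbl.n12 * tbl.n21)
    else:
        odds = math.inf if tbl.n11 * tbl.n22 > 0 else math.nan
    return TestResult(
        raw_p=float(p),
        statistic=odds,
        method="fisher_2t",
        direction=direction,
        warnings=warnings,
    )


def _tie_groups(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts


def wilcoxon_ranksum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of x (query values) vs. y (rest).

    Missing values must already be removed; both sides must be non-empty.
    Exact path: enumerate every assignment of the midranks to the x group
    and double the smaller tail, capping at 1.  Approximate path: normal
    approximation with continuity correction and tie-corrected variance.

    Warnings are attached for small query sides (< 10 values), for rank
    assignment counts >= 2500, and for p >= 0.25.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both sides must be non-empty after missing-value removal")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # midranks for ties
    w = float(ranks[:n].sum())
    n_comb = math.comb(n + m, n)
    warnings: list[str] = []
    if n < SMALL_LIST:
        warnings.append(f"small gene list ({n} values, below {SMALL_LIST})")
    if n_comb >= EXACT_LIMIT:
        warnings.append(f"number of rank assignments >= {EXACT_LIMIT}")

    if n_comb <= exact_limit:
        method = "wilcoxon_exact"
        eps = 1e-9
        n_le = n_ge = 0
        for idx in itertools.combinations(range(n + m), n):
            s = ranks[list(idx)].sum()
            if s <= w + eps:
                n_le += 1
            if s >= w - eps:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / n_comb)
    else:
        method = "wilcoxon_normal"
        total = n + m
        mu = n * (total + 1) / 2.0
        ties = _tie_groups(combined)
        tie_term = float(((ties**3) - ties).sum()) / (total * (total - 1))
        var = n * m / 12.0 * ((total + 1) - tie_term)
        if var <= 0 or w == mu:
            p = 1.0
        else:
            z = (w - mu - 0.5 * math.copysign(1.0, w - mu)) / math.sqrt(var)
            p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    if p >= HIGH_P_WARN:
        warnings.append(f"p >= {HIGH_P_WARN}")
    direction = "over" if float(x.mean()) > float(y.mean()) else "under"
    return TestResult(
        raw_p=p, statistic=w, method=method, direction=direction, warnings=warnings
    )


def interaction_sum(A: Iterable[str], P: InteractionNetwork) -> int:
    """Number of edges of P with both endpoints in A (induced edge count)."""
    aset = set(A)
    return sum(1 for a, b in P.edges if a in aset and b in aset)


def permutation_interaction_test(
    A: Iterable[str],
    P: InteractionNetwork,
    background: Background,
    n_perm: int = 1000,
    seed: int | None = None,
) -> TestResult:
    """Permutation test for interaction enrichment within the query list.

    Each permutation draws |A| genes without replacement from the pool of
    background genes outside A and counts the interactions internal to the
    draw.  With c = number of draws whose sum strictly exceeds the observed
    sum, p = max(c, 1) / n_perm * 2, capped at 1 (so the best attainable p
    at 1000 permutations is 0.002).

    The pool must be at least twice the query size; otherwise no p-value
    can be computed and a warning is returned instead.
    """
    aset = frozenset(A)
    observed = interaction_sum(aset, P)
    pool = sorted(background.genes - aset)
    if len(pool) < 2 * len(aset):
        return TestResult(
            raw_p=None,
            statistic=float(observed),
            method="permutation",
            direction="over",
            warnings=[
                "query list too large: background pool smaller than twice "
                "the query; p-values cannot be computed"
            ],
            details={"observed": observed, "n_perm": n_perm},
        )
    rng = np.random.default_rng(seed)
    index = {g: i for i, g in enumerate(pool)}
    edge_idx = np.array(
        [
            (index[a], index[b])
            for a, b in sorted(P.edges)
            if a in index and b in index
        ],
        dtype=np.intp,
    ).reshape(-1, 2)
    k = len(aset)
    sums = np.zeros(n_perm, dtype=np.int64)
    # chunked fully-vectorized draws: argsort of uniforms gives uniform
    # without-replacement subsets
    chunk = max(1, int(2e7) // max(1, len(pool)))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        draws = rng.random((size, len(pool))).argsort(axis=1)[:, :k]
        member = np.zeros((size, len(pool)), dtype=bool)
        np.put_along_axis(member, draws, True, axis=1)
        if len(edge_idx):
            sums[done : done + size] = (
                member[:, edge_idx[:, 0]] & member[:, edge_idx[:, 1]]
            ).sum(axis=1)
        done += size
    c = int((sums > observed).sum())
    p = min(1.0, 2.0 * max(c, 1) / n_perm)
    warnings: list[str] = []
    if len(aset) < SMALL_LIST:
        warnings.append(f"small gene list ({len(aset)} genes, below {SMALL_LIST})")
    if p >= HIGH_P_WARN:
        warnings.append(f"p >= {HIGH_P_WARN}")
    return TestResult(
        raw_p=p,
        statistic=float(observed),
        method="permutation",
        direction="over",
        warnings=warnings,
        details={
            "observed": observed,
            "exceed_count": c,
            "n_perm": n_perm,
            "perm_mean": float(sums.mean()),
        },
    )


@dataclass
class CorrectionInput:
    """Raw p-values plus the total test count t and the threshold alpha.

    ``t`` must equal the number of p-values submitted: every test performed
    enters the correction exactly once.
    """

    raw_ps: Sequence[float]
    t: int | None = None
    alpha: float = 0.01

    def __post_init__(self) -> None:
        if self.t is None:
            self.t = len(self.raw_ps)
        if self.t != len(self.raw_ps):
            raise ValueError(
                "t must equal the number of submitted p-values "
                f"({self.t} != {len(self.raw_ps)})"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def correct_bonferroni(inp: CorrectionInput) -> list[float]:
    """Bonferroni: each p multiplied by t, capped at 1."""
    if not inp.raw_ps:
        return []
    return list(multipletests(inp.raw_ps, method="bonferroni")[1])


def correct_holm(inp: CorrectionInput) -> list[float]:
    """Holm step-down: sorted p_i x (t - i + 1), monotone, capped at 1."""
    if not inp.raw_ps:
        return []
    return list(multipletests(inp.raw_ps, method="holm")[1])


def correct_bh_fdr(inp: CorrectionInput) -> tuple[list[float], list[bool]]:
    """Benjamini-Hochberg step-up at level alpha.

    Returns the conventional BH-adjusted p-values together with the
    significance flags of the step-up procedure at ``inp.alpha``.
    """
    if not inp.raw_ps:
        return [], []
    reject, adj = multipletests(inp.raw_ps, alpha=inp.alpha, method="fdr_bh")[:2]
    return list(adj), [bool(r) for r in reject]
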