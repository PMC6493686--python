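"""Exact and asymptotic tests used throughout the pipeline.

Conventions fixed here once and reused everywhere:

* two-sided Fisher uses the probability-mass rule (sum over tables no more
  probable than the observed one);
* upper-tail means ``P(X >= k)`` inclusive;
* ``-log(P)`` anywhere in this package means ``-log10(P)``.

scipy provides the distributions; the exact small-sample rank-sum null is
enumerated here with a tie-aware subset-sum DP because scipy's exact method
refuses ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "fisher_exact",
    "hypergeom_overlap",
    "binomial_tail",
    "rank_sum",
    "kruskal_wallis",
    "pearson",
    "bh_qvalues",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sided: str
    method: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(max(self.p_value, np.finfo(float).tiny)))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts [[a, b], [c, d]]; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if min(self.a + self.b, self.c + self.d,
               self.a + self.c, self.b + self.d) == 0:
            raise ValueError("empty margin: test undefined")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_exact(table, sided: str = "two") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    ``sided='one'`` is the upper tail in the ``a`` direction (more
    a-outcomes in the first group than expected under independence).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*np.asarray(table).ravel())
    alternative = {"one": "greater", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise ValueError("sided must be 'one' or 'two'")
    odds, p = sps.fisher_exact(table.as_array(), alternative=alternative)
    return TestResult(float(odds), float(min(p, 1.0)), sided, "fisher_exact")


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> TestResult:
    """Upper-tail ``P(X >= k)`` for X ~ Hypergeometric(N, K, n).

    ``k`` observed overlap between a set of size ``K`` and one of size ``n``
    drawn from a universe of ``N``.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return TestResult(float(k), min(max(p, 0.0), 1.0), "one", "hypergeom_overlap")


def binomial_tail(k: int, n: int, p0: float) -> TestResult:
    """Upper-tail ``P(X >= k)`` for X ~ Binomial(n, p0), log-space stable."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    logp = sps.binom.logsf(k - 1, n, p0)
    p = float(np.exp(logp))
    return TestResult(float(k), min(max(p, 0.0), 1.0), "one", "binomial_tail")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact permutation null of the rank-sum of x, tie-aware.

    DP over which of the combined midranks (doubled to integers) land in x;
    counts arrangements by (#chosen, doubled rank sum).
    """
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)          # midranks; ties -> .5 steps
    r2 = np.rint(ranks * 2).astype(np.int64)
    nx = len(x)
    w_obs = int(r2[:nx].sum())
    total = int(r2.sum())
    # f[j] maps achievable doubled-sum -> count, for j chosen elements
    f = [dict() for _ in range(nx + 1)]
    f[0][0] = 1
    for r in r2:
        for j in range(nx, 0, -1):
            if not f[j - 1]:
                continue
            tgt = f[j]
            for s, c in f[j - 1].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    dist = f[nx]
    n_total = sum(dist.values())
    lower = sum(c for s, c in dist.items() if s <= w_obs) / n_total
    upper = sum(c for s, c in dist.items() if s >= w_obs) / n_total
    if alternative == "less":
        return lower
    if alternative == "greater":
        return upper
    return min(1.0, 2.0 * min(lower, upper))


def rank_sum(
    x,
    y,
    sided: str = "two",
    exact_limit: int = 20,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation null when the combined sample size is at most
    ``exact_limit``; otherwise the normal approximation with tie correction
    and continuity correction. ``sided='less'`` means x tends smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}.get(
        sided
    )
    if alternative is None:
        raise ValueError("sided must be 'two', 'less', or 'greater'")
    w = float(sps.rankdata(np.concatenate([x, y]))[: x.size].sum())
    if np.unique(np.concatenate([x, y])).size == 1:
        warnings.warn("all values identical across both samples; p = 1")
        return TestResult(w, 1.0, sided, "rank_sum_degenerate")
    if x.size + y.size <= exact_limit:
        p = _exact_ranksum_p(x, y, alternative)
        return TestResult(w, p, sided, "rank_sum_exact")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return TestResult(w, float(res.pvalue), sided, "rank_sum_normal_approx")


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction, chi-square tail on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if np.unique(np.concatenate(groups)).size == 1:
        warnings.warn("all values identical across groups; H = 0, p = 1")
        return TestResult(0.0, 1.0, "one", "kruskal_wallis")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(min(p, 1.0)), "one", "kruskal_wallis")


def pearson(x, y) -> tuple[float, TestResult]:
    """Pearson correlation with a t-distribution p-value on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = sps.pearsonr(x, y)
    return float(r), TestResult(float(r), float(min(p, 1.0)), "two", "pearson")


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
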