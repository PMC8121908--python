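"""Dispersion and hypothesis-testing toolkit for ratio tables.

Covers exactly the procedures used on the measured ratios: coefficient of
variation, the two-sided Wilcoxon rank-sum (Mann-Whitney) test with an
exact small-sample path, the two-tailed unpaired Welch t-test, Bonferroni
adjustment, and Bonferroni-corrected pairwise tissue comparisons.

The exact Wilcoxon path enumerates the null distribution of the rank-sum
statistic by dynamic programming and uses the *doubled-tail* two-sided
convention: p = min(1, 2 * min(P(W <= w), P(W >= w))), i.e. the fraction
of group assignments at least as extreme as observed on either side.
This matches R's ``wilcox.test`` exact path; conventions differ between
implementations (some sum all values of no larger point probability,
which can exceed the doubled tail), so the choice is documented here and
mirrored by the enumeration oracle used in the tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: combined sample size at or below which the exact Wilcoxon path is used
EXACT_WILCOXON_CUTOFF = 16


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    adjusted_p: float | None = None
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value:
            raise ValueError("adjusted p below raw p")


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def _ranksum_null_pmf(n1: int, n2: int) -> dict[int, float]:
    """Null pmf of the rank-sum of group 1 (no ties), by DP over ranks."""
    n = n1 + n2
    # ways[k][s]: number of k-subsets of {1..r} with sum s
    ways = [dict() for _ in range(n1 + 1)]
    ways[0][0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            for s, cnt in list(ways[k - 1].items()):
                ways[k][s + rank] = ways[k].get(s + rank, 0) + cnt
    total = math.comb(n, n1)
    return {s: cnt / total for s, cnt in ways[n1].items()}


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> StatResult:
    """Two-sided Wilcoxon rank-sum test.

    The statistic is the sum of (mid)ranks of ``a`` in the pooled sample.
    ``mode`` is ``"auto"`` (exact when the combined n is at most
    :data:`EXACT_WILCOXON_CUTOFF` and there are no ties), ``"exact"`` or
    ``"approx"`` (normal approximation with tie and continuity
    corrections).  Symmetric under swapping the two groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)          # midranks for ties
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    use_exact = (mode == "exact"
                 or (mode == "auto" and n <= EXACT_WILCOXON_CUTOFF
                     and not has_ties))
    if use_exact and has_ties:
        raise ValueError("exact path requires data without ties")
    if use_exact:
        pmf = _ranksum_null_pmf(n1, n2)
        w_int = int(round(w))
        lo = sum(pr for s, pr in pmf.items() if s <= w_int)
        hi = sum(pr for s, pr in pmf.items() if s >= w_int)
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact (doubled-tail two-sided)"
    else:
        mean = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3) - tie_counts).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
            method = "normal approximation (degenerate: all values tied)"
        else:
            # continuity correction of 0.5 toward the mean
            z = (w - mean - math.copysign(0.5, w - mean)) / math.sqrt(var)
            if (w - mean) == 0:
                z = 0.0
            p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
            method = "normal approximation with tie/continuity correction"
    return StatResult(test="wilcoxon_rank_sum", statistic=w,
                      p_value=min(p, 1.0), n1=n1, n2=n2, method=method)


def wilcoxon_exact_oracle(a, b) -> float:
    """Brute-force doubled-tail two-sided p over all group assignments.

    Counts the C(n1+n2, n1) rank splits in each tail at or beyond the
    observed rank sum.  Independent reference for the DP exact path; for
    small samples only.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1 = a.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    lo = hi = total = 0
    for combo in itertools.combinations(range(pooled.size), n1):
        s = float(ranks[list(combo)].sum())
        total += 1
        if s <= w_obs + 1e-9:
            lo += 1
        if s >= w_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def t_test_two_sample(a, b, equal_var: bool = False) -> StatResult:
    """Two-tailed unpaired two-sample t-test (Welch by default).

    Degenerate inputs follow the stated conventions: both groups constant
    with equal means gives p = 1; constant groups with different means
    give p = 0 and a flagged method note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if a.mean() == b.mean():
            return StatResult(test="t_test", statistic=0.0, p_value=1.0,
                              n1=a.size, n2=b.size,
                              method="degenerate: zero variance, equal means")
        return StatResult(test="t_test", statistic=math.inf, p_value=0.0,
                          n1=a.size, n2=b.size,
                          method="degenerate: zero variance, unequal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    method = "pooled-variance t" if equal_var else "Welch t"
    return StatResult(test="t_test", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n1=a.size, n2=b.size,
                      method=method, df=float(res.df))


def bonferroni_adjust(p_values) -> np.ndarray:
    """min(1, m * p) for m comparisons; order-preserving."""
    p = np.asarray(p_values, dtype=float)
    return np.minimum(1.0, p * p.size)


def pairwise_tissue_tests(
    table, tissues, value_col: str = "ratio", group_col: str = "tissue",
    alpha: float = 0.05,
) -> list[StatResult]:
    """Bonferroni-adjusted Wilcoxon rank-sum tests over all tissue pairs.

    ``table`` is a DataFrame; every unordered pair among ``tissues`` is
    tested and the family size is C(k, 2).  Each returned
    :class:`StatResult` carries raw and adjusted p; significance at
    ``alpha`` is assessed on the adjusted value.
    """
    groups = {t: np.asarray(
        table.loc[table[group_col] == t, value_col], dtype=float)
        for t in tissues}
    for t, vals in groups.items():
        if vals.size == 0:
            raise ValueError(f"no values for tissue {t!r}")
    pairs = list(itertools.combinations(tissues, 2))
    raw = [wilcoxon_rank_sum(groups[t1], groups[t2]) for t1, t2 in pairs]
    adj = bonferroni_adjust([r.p_value for r in raw])
    out = []
    for (t1, t2), r, ap in zip(pairs, raw, adj):
        out.append(StatResult(
            test=f"wilcoxon_rank_sum[{t1} vs {t2}]", statistic=r.statistic,
            p_value=r.p_value, adjusted_p=float(ap), n1=r.n1, n2=r.n2,
            method=r.method))
    return out


def significant(results: list[StatResult], alpha: float = 0.05) -> list[bool]:
    return [(r.adjusted_p if r.adjusted_p is not None else r.p_value) < alpha
            for r in results]
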