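"""Core statistical primitives shared across the analysis pipelines.

The Mann-Whitney-Wilcoxon (MWW) test is the workhorse of the burden-association
pipelines.  For small groups (both sizes <= 8) an exact mid-rank permutation
enumeration is used so that p-values with ties are exact; larger groups fall back
to the tie-corrected normal approximation.  The Spearman p-value follows
Algorithm AS 89 (Best & Roberts 1975): exact enumeration of the rank statistic
for n <= 9 and the Edgeworth series expansion for larger n, mirroring the
behaviour of R's ``cor.test``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MWWResult",
    "mww_test",
    "bh_fdr",
    "chi2_2x2",
    "SpearmanResult",
    "spearman_as89",
    "empirical_p",
]


@dataclass(frozen=True)
class MWWResult:
    """Two-sample rank test result: U statistic of the first group and p-value."""

    u: float
    p: float
    method: str
    n1: int
    n2: int


#: group-size bound below which the exact permutation enumeration is used
EXACT_MWW_MAX_N = 8


def _rank_midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _exact_mww_p(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact MWW by enumerating all C(n1+n2, n1) group labelings on mid-ranks.

    Valid with ties; cost C(16, 8) = 12870 at the size bound.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _rank_midranks(pooled)
    total = ranks.sum()
    # U for group 1 from its rank sum
    obs_r1 = ranks[:n1].sum()
    obs_u = obs_r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    count = 0
    n_lab = 0
    idx = range(n1 + n2)
    for comb in combinations(idx, n1):
        r1 = ranks[list(comb)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        n_lab += 1
        if alternative == "two-sided":
            if abs(u - mu) >= abs(obs_u - mu) - 1e-12:
                count += 1
        elif alternative == "greater":
            if u >= obs_u - 1e-12:
                count += 1
        else:  # less
            if u <= obs_u + 1e-12:
                count += 1
    del total
    return obs_u, count / n_lab


def mww_test(x, y, alternative: str = "two-sided") -> MWWResult:
    """Two-sample Mann-Whitney-Wilcoxon test.

    Parameters
    ----------
    x, y
        Sample values (1-d, any real values; ties allowed).
    alternative
        ``"two-sided"`` (default), ``"greater"`` or ``"less"``; directions refer
        to the distribution of ``x`` relative to ``y``.

    Exact permutation enumeration is used when both groups have at most
    :data:`EXACT_MWW_MAX_N` observations, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size <= EXACT_MWW_MAX_N and y.size <= EXACT_MWW_MAX_N:
        u, p = _exact_mww_p(x, y, alternative)
        return MWWResult(u=float(u), p=float(min(p, 1.0)), method="exact",
                         n1=x.size, n2=y.size)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic",
                           use_continuity=True)
    return MWWResult(u=float(res.statistic), p=float(res.pvalue),
                     method="asymptotic", n1=x.size, n2=y.size)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (same order as the input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi2_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table -> (statistic, p).

    Yates continuity correction is off by default; the intended use is tables
    with large expected counts.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("empty table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=yates)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Spearman correlation with AS 89 p-values
# ---------------------------------------------------------------------------

# Edgeworth-series coefficients of Best & Roberts (1975)
_AS89_C = (0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932,
           0.0879, 0.0151, 0.0072, 0.0831, 0.0267, 0.04567)


def _as89_upper(n: int, s: float) -> float:
    """Edgeworth-series approximation of Pr(S >= s) for Spearman's S."""
    c1, c2, c3, c4, c5, c6, c7, c8, c9, c10, c11, c12 = _AS89_C
    b = 1.0 / n
    x = (6.0 * (s - 1.0) * b / (n * n - 1.0) - 1.0) * math.sqrt(1.0 / b - 1.0)
    y = x * x
    u = x * b * (c1 + b * (c2 + c3 * b)
                 + y * (-c4 + b * (c5 + c6 * b)
                        - y * b * (c7 + c8 * b
                                   - y * (c9 - c10 * b
                                          + y * b * (c11 - c12 * y)))))
    p = u / math.exp(y / 2.0) + 0.5 * math.erfc(x / math.sqrt(2.0))
    return min(1.0, max(0.0, p))


def _exact_s_tail(n: int, s: float, upper: bool) -> float:
    """Exact Pr(S >= s) (or <=) by enumerating all n! rank permutations."""
    base = np.arange(1, n + 1)
    count = 0
    total = 0
    for perm in permutations(range(1, n + 1)):
        ss = sum((a - b) ** 2 for a, b in zip(base, perm))
        total += 1
        if (upper and ss >= s - 1e-9) or (not upper and ss <= s + 1e-9):
            count += 1
    return count / total


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    s: float
    n: int
    method: str


def spearman_as89(x, y, alternative: str = "two-sided",
                  method: str = "auto") -> SpearmanResult:
    """Spearman rank correlation with an AS 89 p-value.

    ``method`` is one of ``"auto"`` (exact enumeration for n <= 9, Edgeworth
    series otherwise), ``"exact"`` or ``"edgeworth"``.  With ties in either
    vector the rank statistic S is no longer integer-valued and the t
    approximation is used instead (as R's ``cor.test`` does).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("correlation undefined: a vector is constant in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    s = float(np.sum((rx - ry) ** 2))

    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if ties:
        # t approximation on rho (AS89 assumes untied ranks)
        t = rho * math.sqrt((n - 2) / max(1e-12, 1.0 - rho * rho))
        p_greater = float(sps.t.sf(t, df=n - 2))
        meth = "t-approx"
    else:
        if method == "auto":
            method = "exact" if n <= 9 else "edgeworth"
        if method == "exact":
            p_upper = _exact_s_tail(n, s, upper=True)
            p_lower = _exact_s_tail(n, s, upper=False)
            meth = "exact"
        elif method == "edgeworth":
            # mirror R's continuity handling: lower tail evaluated at S + 2
            p_upper = _as89_upper(n, s)
            p_lower = 1.0 - _as89_upper(n, s + 2.0)
            meth = "edgeworth"
        else:
            raise ValueError(f"unknown method {method!r}")
        # large S = negative association; p for "greater" is the lower tail of S
        p_greater = p_lower

    if ties:
        p_less = 1.0 - p_greater
        p_two = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        p_less = p_upper
        p_two = min(1.0, 2.0 * min(p_greater, p_less))

    p = {"two-sided": p_two, "greater": p_greater, "less": p_less}[alternative]
    return SpearmanResult(rho=rho, p=float(p), s=s, n=n, method=meth)


def empirical_p(null_stats, observed: float, alternative: str = "greater") -> float:
    """Add-one empirical p-value: (1 + #{null >= obs}) / (1 + n).

    The add-one correction keeps the p-value strictly positive, which is the
    conservative convention for Monte-Carlo tests.
    """
    null = np.asarray(null_stats, dtype=float)
    if alternative == "greater":
        k = int(np.sum(null >= observed))
    elif alternative == "less":
        k = int(np.sum(null <= observed))
    else:
        raise ValueError("alternative must be 'greater' or 'less'")
    return (1.0 + k) / (1.0 + null.size)
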