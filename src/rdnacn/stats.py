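"""Exact nonparametric tests used throughout the pipeline.

All hypothesis tests in the package funnel through this module so that the
choice between exact enumeration and large-sample approximation is made in one
place and is logged per call.  The conventions are:

* paired comparisons use the Wilcoxon signed-rank test (exact null for small
  n, normal approximation with continuity correction otherwise);
* two-group comparisons use the Wilcoxon rank-sum (Mann-Whitney U) test with
  the same exact/approximate switch;
* direction-of-effect aggregation uses the exact binomial test against
  p = 0.5, two-sided by the point-probability (minlike) rule, which at
  p = 0.5 equals twice the smaller tail.

Zero paired differences are dropped before ranking by default ("wilcox"
handling); Pratt handling is available via ``zero_method="pratt"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: largest per-group / per-pair-set size for which the exact null is enumerated
EXACT_MAX = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    pvalue: float
    n: int
    method: str  # "exact" or "approx"

    def __iter__(self):  # allow  stat, p = result
        return iter((self.statistic, self.pvalue))


def signed_rank_test(
    x,
    y=None,
    alternative: str = "two-sided",
    zero_method: str = "wilcox",
    exact_max: int = EXACT_MAX,
) -> TestResult:
    """Wilcoxon signed-rank test on paired data (or differences directly).

    Parameters
    ----------
    x, y
        Paired measurements; if ``y`` is None, ``x`` is taken to be the
        vector of differences.
    alternative
        "two-sided", "greater" (x > y) or "less".
    zero_method
        "wilcox" drops zero differences before ranking (default); "pratt"
        keeps them in the ranking but drops their ranks.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size == 0:
        raise ValueError("no pairs provided")
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        # all ties: no evidence either way
        return TestResult(0.0, 1.0, 0, "degenerate")
    method = "exact" if n_nonzero <= exact_max else "approx"
    res = sps.wilcoxon(
        d,
        alternative=alternative,
        zero_method=zero_method,
        correction=(method == "approx"),
        method=method,
    )
    logger.debug("signed-rank n=%d method=%s p=%.3g", n_nonzero, method, res.pvalue)
    return TestResult(float(res.statistic), float(res.pvalue), n_nonzero, method)


def rank_sum_test(
    x,
    y,
    alternative: str = "two-sided",
    exact_max: int = EXACT_MAX,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test between two groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if max(x.size, y.size) <= exact_max and not ties else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    n = int(x.size + y.size)
    logger.debug("rank-sum n=%d method=%s p=%.3g", n, method, res.pvalue)
    return TestResult(float(res.statistic), float(res.pvalue), n, method)


def binomial_direction_test(
    k: int, n: int, alternative: str = "two-sided"
) -> TestResult:
    """Exact binomial test of k successes in n trials against p = 0.5.

    Two-sided p-values use the point-probability rule: the sum of all
    outcome probabilities no larger than that of the observed count, which
    at p = 0.5 equals twice the smaller tail.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    res = sps.binomtest(int(k), int(n), p=0.5, alternative=alternative)
    return TestResult(float(k), float(res.pvalue), int(n), "exact")


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return TestResult(np.nan, np.nan, int(ok.sum()), "degenerate")
    rho, p = sps.spearmanr(x[ok], y[ok])
    return TestResult(float(rho), float(p), int(ok.sum()), "asymptotic")


def pearson(x, y) -> TestResult:
    """Pearson correlation with two-sided p; NaN-safe pairwise deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return TestResult(np.nan, np.nan, int(ok.sum()), "degenerate")
    r, p = sps.pearsonr(x[ok], y[ok])
    return TestResult(float(r), float(p), int(ok.sum()), "asymptotic")
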