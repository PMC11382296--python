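"""Nonparametric tests and effect sizes for per-subject summaries.

All tests operate on small per-subject vectors (medians, occurrence
percentages) and are thin, contract-checked wrappers around scipy:

* Wilcoxon signed-rank for paired contrasts, with effect size
  ``r = |Z| / sqrt(N)`` from the normal-approximation Z (continuity
  corrected, average ranks for ties);
* Kruskal-Wallis for independent groups, with effect size
  ``eta² = H / (N − 1)`` (``H / N`` available behind a flag);
* Friedman for complete subjects-by-conditions blocks;
* chi-squared goodness of fit to a fitted normal, Pearson correlation
  and a two-sample Kolmogorov-Smirnov wrapper as auxiliaries.

No multiple-testing correction is applied anywhere; all p-values are
raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult", "wilcoxon_paired", "kruskal_wallis_groups",
    "friedman_blocks", "chi_square_normality", "pearson_correlation",
    "ks_two_sample",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical test.

    ``effect_size`` is ``r`` (Wilcoxon, absolute value in [0, 1]) or
    ``eta²`` (Kruskal-Wallis) where defined, else None.  ``flagged``
    marks degenerate inputs (e.g. all-zero paired differences) whose
    statistic is undefined rather than zero.
    """

    method: str
    statistic: float
    p_value: float
    n: int
    effect_size: Optional[float] = None
    effect_size_name: Optional[str] = None
    flagged: bool = False
    note: str = ""


def wilcoxon_paired(x, y, exact: bool = False) -> TestResult:
    """Wilcoxon signed-rank test for paired samples with effect size r.

    ``r = |Z| / sqrt(N)`` where Z is the continuity-corrected normal
    approximation and N the number of pairs.  With ``exact=True`` the
    p-value uses the exact signed-rank distribution (N <= 25, no ties);
    the effect size still comes from the approximation Z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 pairs")
    diffs = x - y
    if np.all(diffs == 0):
        return TestResult(method="wilcoxon", statistic=float("nan"),
                          p_value=float("nan"), n=n, flagged=True,
                          note="all paired differences are zero; Z undefined")
    approx = sps.wilcoxon(x, y, correction=True, method="approx")
    z = float(approx.zstatistic)
    r = abs(z) / np.sqrt(n)
    if exact:
        if n > 25:
            raise ValueError("exact p-value supported for N <= 25 only")
        res = sps.wilcoxon(x, y, method="exact")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        stat, p = float(approx.statistic), float(approx.pvalue)
    return TestResult(method="wilcoxon", statistic=stat, p_value=p, n=n,
                      effect_size=float(r), effect_size_name="r")


def kruskal_wallis_groups(groups, prose_denominator: bool = False) -> TestResult:
    """Kruskal-Wallis H test across independent groups with eta².

    ``groups`` is a sequence of 1-d value arrays (one per label).
    ``eta² = H / (N − 1)`` with N the total sample size; with
    ``prose_denominator=True`` the variant ``H / N`` is used instead.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    n = sum(a.size for a in arrays)
    if n < 5:
        raise ValueError("need at least 5 observations in total")
    h, p = sps.kruskal(*arrays)
    denom = n if prose_denominator else n - 1
    return TestResult(method="kruskal_wallis", statistic=float(h), p_value=float(p),
                      n=n, effect_size=float(h) / denom, effect_size_name="eta_squared")


def friedman_blocks(matrix) -> TestResult:
    """Friedman chi-square test on a complete subjects × conditions matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("matrix must be 2-d with at least 2 conditions")
    if m.shape[0] < 5:
        raise ValueError("need at least 5 subjects (rows)")
    if np.isnan(m).any():
        raise ValueError("matrix has missing cells; no imputation is performed")
    if np.all(m == m[:, [0]]):
        # identical conditions: statistic is 0 by construction
        return TestResult(method="friedman", statistic=0.0, p_value=1.0,
                          n=m.shape[0], flagged=True,
                          note="all condition columns identical")
    stat, p = sps.friedmanchisquare(*m.T)
    return TestResult(method="friedman", statistic=float(stat), p_value=float(p),
                      n=m.shape[0])


def chi_square_normality(x, n_bins: Optional[int] = None) -> TestResult:
    """Chi-squared goodness of fit of a sample to a fitted normal.

    The sample is binned (default ``ceil(2 * n**0.4)`` equal-probability
    bins under the fitted normal), expected counts come from the normal
    with the sample mean and SD, and the statistic loses two degrees of
    freedom for the estimated parameters.  Fewer than 3 bins with
    expected count >= 5 flags the result instead of testing.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return TestResult(method="chi_square_normality", statistic=float("nan"),
                          p_value=float("nan"), n=x.size, flagged=True,
                          note="zero variance")
    k = n_bins or int(np.ceil(2 * x.size ** 0.4))
    # equal-probability bins under the fitted normal
    edges = sps.norm.ppf(np.linspace(0, 1, k + 1), loc=mu, scale=sd)
    observed, _ = np.histogram(x, bins=edges)
    expected = np.full(k, x.size / k)
    usable = int((expected >= 5).sum())
    if usable < 3:
        return TestResult(method="chi_square_normality", statistic=float("nan"),
                          p_value=float("nan"), n=x.size, flagged=True,
                          note="fewer than 3 bins with expected count >= 5")
    stat, p = sps.chisquare(observed, expected, ddof=2)
    return TestResult(method="chi_square_normality", statistic=float(stat),
                      p_value=float(p), n=x.size)


def pearson_correlation(x, y) -> TestResult:
    """Pearson correlation coefficient with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with at least 3 points")
    res = sps.pearsonr(x, y)
    return TestResult(method="pearson", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=x.size)


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test."""
    res = sps.ks_2samp(np.asarray(x, float), np.asarray(y, float))
    return TestResult(method="ks_2samp", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=len(x))
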