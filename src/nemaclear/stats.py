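"""Rank-based and parametric tests used by the analysis modules.

Self-contained, deterministic implementations of the procedures the
pipeline needs: the Wilcoxon rank-sum test with an exact small-sample
permutation option, the Kruskal-Wallis omnibus with Bonferroni-corrected
pairwise comparisons, one-way ANOVA with pairwise pooled-variance t tests,
the Anderson-Darling normality check (case 3: mean and SD estimated), and
ordinary least squares with a t-based confidence interval on the slope.
SciPy supplies only distribution functions (CDFs/quantiles), never the test
logic, so each procedure can be cross-checked independently.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import List, NamedTuple, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import f as _fdist
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata
from scipy.stats import t as _tdist

__all__ = [
    "TestResult",
    "LinFit",
    "rank_sum",
    "kruskal_wallis",
    "pairwise_vs_control",
    "anova_bonferroni",
    "anderson_darling",
    "linreg_ci",
]


@dataclasses.dataclass
class TestResult:
    """Outcome of a hypothesis test (two-sided p throughout)."""

    statistic: float
    p: float
    method: str
    n: tuple
    correction: str = "none"
    factor: int = 1
    p_raw: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


class LinFit(NamedTuple):
    slope: float
    intercept: float
    slope_ci: tuple
    se_slope: float
    r_squared: float


def _check_group(g, name: str, min_n: int = 2) -> np.ndarray:
    g = np.asarray(g, dtype=float).ravel()
    if len(g) < min_n:
        raise ValueError(f"group {name} needs at least {min_n} values")
    if not np.all(np.isfinite(g)):
        raise ValueError(f"group {name} contains non-finite values")
    return g


def rank_sum(a, b, exact_max_n: int = 10) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    When both groups have at most ``exact_max_n`` observations the p-value
    is computed exactly by enumerating every assignment of the pooled ranks
    and counting rank sums at least as far from their null mean as the
    observed one.  Otherwise a tie-corrected normal approximation with
    continuity correction is used.  Identical pooled values give p = 1.
    """
    a = _check_group(a, "a")
    b = _check_group(b, "b")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return TestResult(statistic=float(na * (na + nb + 1) / 2), p=1.0,
                          method="rank-sum (degenerate)", n=(na, nb))
    ranks = _rankdata(pooled)
    w = float(ranks[:na].sum())
    mu = na * (na + nb + 1) / 2.0
    if na <= exact_max_n and nb <= exact_max_n:
        dev = abs(w - mu) - 1e-9
        count = 0
        total = 0
        for comb in itertools.combinations(range(na + nb), na):
            total += 1
            if abs(ranks[list(comb)].sum() - mu) >= dev:
                count += 1
        return TestResult(statistic=w, p=count / total,
                          method="rank-sum (exact)", n=(na, nb))
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / ((n) * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=w, p=1.0, method="rank-sum (degenerate)", n=(na, nb))
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = float(min(1.0, 2 * _norm.sf(max(z, 0.0))))
    return TestResult(statistic=w, p=p, method="rank-sum (normal approx)", n=(na, nb))


def kruskal_wallis(groups: Sequence) -> TestResult:
    """Kruskal-Wallis H test with tie correction; chi-square p-value."""
    groups = [_check_group(g, str(i)) for i, g in enumerate(groups)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    n = len(pooled)
    if np.ptp(pooled) == 0:
        return TestResult(statistic=0.0, p=1.0, method="Kruskal-Wallis (degenerate)",
                          n=tuple(sizes))
    ranks = _rankdata(pooled)
    h = 0.0
    start = 0
    for sz in sizes:
        rsum = ranks[start:start + sz].sum()
        h += rsum**2 / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if correction <= 0:
        return TestResult(statistic=0.0, p=1.0, method="Kruskal-Wallis (degenerate)",
                          n=tuple(sizes))
    h /= correction
    p = float(_chi2.sf(h, len(groups) - 1))
    return TestResult(statistic=float(h), p=p, method="Kruskal-Wallis", n=tuple(sizes))


def pairwise_vs_control(
    groups: Sequence,
    control_index: int = 0,
    method: str = "rank_sum",
) -> List[TestResult]:
    """Pairwise comparisons against a control group, Bonferroni corrected.

    The Bonferroni factor is the number of comparisons actually performed
    (number of non-control groups) and is recorded in each result.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    others = [i for i in range(len(groups)) if i != control_index]
    factor = len(others)
    results = []
    for i in others:
        if method == "rank_sum":
            res = rank_sum(groups[i], groups[control_index])
        elif method == "t":
            res = _pooled_t(groups[i], groups[control_index])
        else:
            raise ValueError(f"unknown pairwise method {method!r}")
        res.p_raw = res.p
        res.p = min(1.0, res.p * factor)
        res.correction = "bonferroni"
        res.factor = factor
        results.append(res)
    return results


def _pooled_t(a, b) -> TestResult:
    a = _check_group(a, "a")
    b = _check_group(b, "b")
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    if sp2 <= 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        return TestResult(statistic=0.0 if p == 1.0 else float("inf"), p=p,
                          method="two-sample t (degenerate)", n=(na, nb))
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = float(min(1.0, 2 * _tdist.sf(abs(t), df)))
    return TestResult(statistic=float(t), p=p, method="two-sample t (pooled)", n=(na, nb))


def anova_bonferroni(groups: Sequence) -> List[TestResult]:
    """One-way ANOVA followed by Bonferroni-corrected pairwise t tests.

    The first result is the omnibus F test; the remaining entries are all
    pairwise pooled-variance t comparisons with Bonferroni factor equal to
    the number of pairs.  With exactly two groups, F = t^2.
    """
    groups = [_check_group(g, str(i)) for i, g in enumerate(groups)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([len(g) for g in groups])
    n = int(sizes.sum())
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_b, df_w = len(groups) - 1, n - len(groups)
    if ss_within <= 0:
        if ss_between <= 0:
            omnibus = TestResult(statistic=0.0, p=1.0, method="one-way ANOVA (degenerate)",
                                 n=tuple(int(s) for s in sizes))
        else:
            omnibus = TestResult(statistic=float("inf"), p=0.0, method="one-way ANOVA",
                                 n=tuple(int(s) for s in sizes))
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        omnibus = TestResult(statistic=float(f), p=float(_fdist.sf(f, df_b, df_w)),
                             method="one-way ANOVA", n=tuple(int(s) for s in sizes))
    results = [omnibus]
    pairs = list(itertools.combinations(range(len(groups)), 2))
    for i, j in pairs:
        res = _pooled_t(groups[i], groups[j])
        res.p_raw = res.p
        res.p = min(1.0, res.p * len(pairs))
        res.correction = "bonferroni"
        res.factor = len(pairs)
        results.append(res)
    return results


#: Stephens' case-3 critical value for the corrected A^2 at alpha = 0.05
AD_CRITICAL_05 = 0.752


def anderson_darling(x) -> tuple:
    """Anderson-Darling normality statistic and decision at alpha = 0.05.

    Mean and SD are estimated from the sample (case 3); the statistic is
    corrected as ``A2 * (1 + 0.75/n + 2.25/n^2)`` and compared with the 0.752
    critical value.  Returns ``(A2_corrected, is_normal)``.  Zero-variance
    samples are non-normal by convention; n < 5 raises.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 5:
        raise ValueError("Anderson-Darling needs at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        return float("inf"), False
    z = np.sort((x - x.mean()) / sd)
    cdf = _norm.cdf(z)
    eps = 1e-15
    cdf = np.clip(cdf, eps, 1 - eps)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log(1 - cdf[::-1])))
    a2_star = float(a2 * (1 + 0.75 / n + 2.25 / n**2))
    return a2_star, a2_star <= AD_CRITICAL_05


def linreg_ci(x, y, alpha: float = 0.05) -> LinFit:
    """Ordinary least squares with a t-based CI on the slope.

    Requires at least 3 points with non-degenerate x.  For a perfect linear
    relationship the residual variance, and hence the CI width, is zero.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 (x, y) points")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx <= 0:
        raise ValueError("x values are degenerate")
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    dof = len(x) - 2
    s2 = float((resid**2).sum() / dof)
    se = math.sqrt(s2 / sxx)
    tcrit = float(_tdist.ppf(1 - alpha / 2, dof))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return LinFit(slope=slope, intercept=intercept,
                  slope_ci=(slope - tcrit * se, slope + tcrit * se),
                  se_slope=se, r_squared=r2)
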