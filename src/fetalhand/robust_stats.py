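"""Robust statistical primitives used throughout the analysis.

Hodges-Lehmann two-sample location estimator, the Welch U-test (Welch's t
on pooled mid-ranks), Benjamini-Hochberg FDR control, plus Spearman,
Pearson, exact binomial, and the Wilcoxon rank-sum test.  Ties receive
mid-ranks everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from scipy import stats

from fetalhand.errors import DegenerateDataError, ValidationError

#: Largest number of group assignments enumerated by the exact rank-sum test.
_EXACT_RANKSUM_LIMIT = 200_000


@dataclass(frozen=True)
class TestResult:
    """Estimate + statistic + raw (and optionally FDR-adjusted) p-value."""

    estimate: float
    statistic: float
    df: float
    p_raw: float
    method: str
    p_adjusted: float | None = None

    def with_adjusted(self, p_adjusted: float) -> "TestResult":
        return replace(self, p_adjusted=float(p_adjusted))


def _as_sample(x, name: str, min_n: int = 1) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < min_n:
        raise ValidationError(f"{name}: need at least {min_n} values, got {a.size}")
    return a


def hodges_lehmann(x, y) -> float:
    """Median of all cross-sample pairwise differences x_i - y_j."""
    xa = _as_sample(x, "x")
    ya = _as_sample(y, "y")
    return float(np.median(np.subtract.outer(xa, ya)))


def welch_u_test(x, y) -> TestResult:
    """Welch's t-test applied to the pooled mid-ranks of the two samples.

    Rank-transform construction: pool both samples, assign mid-ranks, then
    run Welch's unequal-variance t with Welch-Satterthwaite df on the two
    rank samples.  Tests stochastic dominance without assuming normality or
    homoscedasticity.  The estimate field carries the Hodges-Lehmann
    location difference x - y in the input units.
    """
    xa = _as_sample(x, "x", min_n=2)
    ya = _as_sample(y, "y", min_n=2)
    est = hodges_lehmann(xa, ya)
    pooled = np.concatenate([xa, ya])
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 0.0, math.nan, 1.0, "welch-u")
    ranks = stats.rankdata(pooled)
    rx, ry = ranks[: xa.size], ranks[xa.size :]
    if np.var(rx, ddof=1) == 0 and np.var(ry, ddof=1) == 0:
        # All ranks tied within each sample but the samples differ: the rank
        # separation is total; report the smallest representable p.
        sign = 1.0 if rx.mean() > ry.mean() else -1.0
        return TestResult(est, sign * math.inf, math.nan, 0.0, "welch-u")
    res = stats.ttest_ind(rx, ry, equal_var=False)
    return TestResult(est, float(res.statistic), float(res.df), float(res.pvalue), "welch-u")


def benjamini_hochberg(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (adjusted p-values, rejection flags).  The adjusted p for the
    i-th smallest raw p is min over j >= i of m * p_(j) / j, capped at 1;
    hypotheses with adjusted p <= q are rejected.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValidationError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation and its two-sided p-value.

    Pearson correlation of mid-ranks; p from the t approximation.
    """
    xa = _as_sample(x, "x", min_n=3)
    ya = _as_sample(y, "y", min_n=3)
    if xa.size != ya.size:
        raise ValidationError("samples must be paired")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("spearman undefined for constant input")
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    xa = _as_sample(x, "x", min_n=2)
    ya = _as_sample(y, "y", min_n=2)
    if xa.size != ya.size:
        raise ValidationError("samples must be paired")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("pearson undefined for constant input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method).

    Sums the probabilities of all outcomes whose probability under
    Binomial(n, p0) does not exceed that of the observed k.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValidationError("p0 must lie in (0, 1)")
    return float(stats.binomtest(int(k), int(n), p0).pvalue)


def _ranksum_exact_p(ranks: np.ndarray, nx: int, observed: float) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    n = ranks.size
    sums = np.fromiter(
        (ranks[list(c)].sum() for c in combinations(range(n), nx)),
        dtype=float,
        count=math.comb(n, nx),
    )
    lo = np.mean(sums <= observed + 1e-12)
    hi = np.mean(sums >= observed - 1e-12)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation enumeration when the number of group assignments is
    small enough; otherwise the normal approximation with continuity and
    tie corrections.  The estimate field carries the Hodges-Lehmann
    difference x - y.
    """
    xa = _as_sample(x, "x", min_n=1)
    ya = _as_sample(y, "y", min_n=1)
    est = hodges_lehmann(xa, ya)
    pooled = np.concatenate([xa, ya])
    nx, n = xa.size, pooled.size
    ranks = stats.rankdata(pooled)
    w = float(ranks[:nx].sum())
    if np.ptp(pooled) == 0:
        return TestResult(0.0, w, math.nan, 1.0, "ranksum-exact")

    if math.comb(n, nx) <= _EXACT_RANKSUM_LIMIT:
        p = _ranksum_exact_p(ranks, nx, w)
        return TestResult(est, w, math.nan, p, "ranksum-exact")

    ny = n - nx
    mean_w = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return TestResult(est, w, math.nan, 1.0, "ranksum-normal")
    shift = w - mean_w
    z = (shift - math.copysign(0.5, shift)) / math.sqrt(var_w) if shift != 0 else 0.0
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return TestResult(est, w, math.nan, p, "ranksum-normal")
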