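"""Nonparametric statistics used throughout the pipeline.

Thin, validated wrappers around scipy/statsmodels that fix the exact
conventions the rest of the package relies on:

* Wilcoxon rank-sum: exact permutation distribution for small tie-free
  samples (combined n <= 12), otherwise the normal approximation with
  tie and continuity corrections.  The reported statistic is the
  rank-sum W of the first sample.
* Pearson correlation with explicit degenerate-input errors.
* Fisher's exact test on a 2x2 table (two-sided by summing hypergeometric
  probabilities no larger than the observed table's).
* Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "pearson",
    "fisher_exact_2x2",
    "benjamini_hochberg",
    "EXACT_MAX_N",
]

EXACT_MAX_N = 12  # combined sample size at or below which the exact test runs


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    alternative: str


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact when ``len(x) + len(y) <= EXACT_MAX_N`` and the pooled data are
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.  Ties always force the approximation so the
    p-value stays well defined and the runtime bounded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateDataError("wilcoxon_rank_sum: empty sample")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (pooled.size <= EXACT_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    n1, n2 = x.size, y.size
    rank_sum = float(res.statistic) + n1 * (n1 + 1) / 2.0
    return TestResult(
        statistic=rank_sum,
        p_value=float(min(res.pvalue, 1.0)),
        method="wilcoxon-rank-sum-exact" if exact else "wilcoxon-rank-sum-normal",
        n1=n1,
        n2=n2,
        alternative=alternative,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Product-moment correlation coefficient and the sample size used."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("pearson: samples differ in length")
    if x.size < 3:
        raise DegenerateDataError(f"pearson: need n >= 3, got n = {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("pearson: zero variance in one of the samples")
    r = float(sps.pearsonr(x, y).statistic)
    return r, int(x.size)


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> TestResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]]."""
    cells = (a, b, c, d)
    if any(int(v) != v or v < 0 for v in cells):
        raise ValidationError(f"fisher_exact_2x2: cells must be non-negative integers: {cells}")
    if sum(cells) == 0:
        raise DegenerateDataError("fisher_exact_2x2: empty table")
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return TestResult(
        statistic=float(odds),
        p_value=float(min(p, 1.0)),
        method="fisher-exact",
        n1=a + b,
        n2=c + d,
        alternative=alternative,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1,
    order-preserving with the input)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("benjamini_hochberg: p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
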