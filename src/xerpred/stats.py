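"""Univariate screening and paired-comparison statistics.

Thin, uniformly-typed wrappers over scipy for the rank and contingency
tests used in the analysis, plus the mid-p McNemar test for comparing
paired classifier accuracies, which is authored here: for discordant
counts (b, c) and n = b + c, with X ~ Binomial(n, 1/2),

    mid-p = 2·[ P(X ≥ max(b, c)) − ½·P(X = max(b, c)) ],  capped at 1.

The half-weight on the observed count makes the test less conservative
than the exact binomial McNemar while keeping its discreteness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


_EXACT_MW_N = 8


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when both groups have n ≤ 8 (and no ties); normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (x.size <= _EXACT_MW_N and y.size <= _EXACT_MW_N) else "asymptotic"
    if method == "exact" and np.unique(np.concatenate([x, y])).size < x.size + y.size:
        method = "asymptotic"  # ties: exact null distribution unavailable
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"mann-whitney-{method}", (x.size, y.size))


def wilcoxon_signed_rank(paired_diffs) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped; exact for n ≤ 25, normal approximation
    otherwise.  All-zero differences give the degenerate p = 1.
    """
    d = np.asarray(paired_diffs, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        return TestResult(0.0, 1.0, "wilcoxon-degenerate", (0,))
    method = "exact" if nz.size <= 25 else "approx"
    if method == "exact" and np.unique(np.abs(nz)).size < nz.size:
        method = "approx"  # tied ranks: no exact distribution
    res = sps.wilcoxon(nz, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"wilcoxon-{method}", (nz.size,))


def chi_squared(table) -> TestResult:
    """Pearson chi-squared test of independence (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate margins: a row or column sums to zero")
    res = sps.chi2_contingency(t, correction=False)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "pearson-chi2", tuple(int(s) for s in t.sum(axis=1)))


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.spearmanr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "spearman", (x.size,))


def midp_mcnemar(b: int, c: int) -> TestResult:
    """Mid-p McNemar test on discordant pair counts (b, c).

    Symmetric in (b, c); n = 0 gives p = 1 by convention.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ValueError("discordant counts must be non-negative integers")
    b, c = int(b), int(c)
    n = b + c
    if b == c:  # symmetric discordance: the two-sided mid-p caps at 1 exactly
        return TestResult(float(b), 1.0, "midp-mcnemar", (b, c))
    m = max(b, c)
    p = 2.0 * (sps.binom.sf(m - 1, n, 0.5) - 0.5 * sps.binom.pmf(m, n, 0.5))
    return TestResult(float(m), float(min(p, 1.0)), "midp-mcnemar", (b, c))
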