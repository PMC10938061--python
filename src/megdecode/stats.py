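"""Paired statistics and chance bands for decoder comparisons.

Replicates (simulated datasets with distinct seeds) play the role
subjects play in real group studies: method accuracies are paired
within replicate and compared with Wilcoxon signed-rank tests,
Bonferroni corrected across the number of comparisons (e.g. x90
across sliding windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats


@dataclass
class PairedAccuracy:
    """Aligned per-replicate mean validation accuracies of two methods."""

    a: np.ndarray
    b: np.ndarray
    name_a: str = "a"
    name_b: str = "b"

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape:
            raise ValueError("paired vectors must have equal length")


@dataclass
class TestResult:
    statistic: float
    p: float
    p_corrected: float
    n_comparisons: int


def wilcoxon_signed_rank(paired, b=None, alternative: str = "two-sided",
                         n_comparisons: int = 1) -> TestResult:
    """Wilcoxon signed-rank test on paired accuracies.

    Zero differences are discarded (Wilcoxon's convention).  The exact
    null distribution is used for n <= 25 without ties; otherwise the
    normal approximation with tie correction.  If every difference is
    zero the test is degenerate and p = 1 is returned with a warning.
    """
    if isinstance(paired, PairedAccuracy):
        x, y = paired.a, paired.b
    else:
        x, y = np.asarray(paired, dtype=float), np.asarray(b, dtype=float)
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1", RuntimeWarning)
        return TestResult(0.0, 1.0, 1.0, n_comparisons)
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not ties) else "approx"
    res = scipy.stats.wilcoxon(nz, alternative=alternative, method=method,
                               zero_method="wilcox")
    p_corr = bonferroni(float(res.pvalue), n_comparisons)
    return TestResult(float(res.statistic), float(res.pvalue), p_corr,
                      n_comparisons)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def chance_band(n_classes: int, n_eval: int, level: float = 0.95):
    """Two-sided binomial interval for the accuracy of a chance decoder.

    Exact binomial quantiles of Binomial(n_eval, 1/n_classes) / n_eval.
    """
    if n_eval < 1:
        raise ValueError("n_eval must be >= 1")
    p = 1.0 / n_classes
    alpha = (1 - level) / 2
    lo = scipy.stats.binom.ppf(alpha, n_eval, p) / n_eval
    hi = scipy.stats.binom.ppf(1 - alpha, n_eval, p) / n_eval
    return float(lo), float(hi)
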