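"""Thin inferential layer shared by the analysis modules.

Wraps scipy/statsmodels with a uniform :class:`TestResult` record.  All
tests are two-sided; the two-sample comparison assumes equal variances
(no Welch correction).  The two-way ANOVA is delegated to statsmodels
OLS + ``anova_lm`` and exposed as a contract: factor F statistics and
p-values only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "paired_compare",
    "two_sample_compare",
    "pearson",
    "ks_compare",
    "bonferroni",
    "two_way_anova",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """Raised when a test statistic is undefined (e.g. zero variance)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float | None
    n: int
    correction: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p out of range: {self.p}")


def _as_arrays(*xs):
    return [np.asarray(x, dtype=float) for x in xs]


def paired_compare(a, b) -> TestResult:
    """Two-sided paired t-test; identical inputs give statistic 0, p = 1."""
    a, b = _as_arrays(a, b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("paired inputs must have equal length >= 2")
    d = a - b
    if np.allclose(d, d[0]) and np.isclose(d[0], 0.0):
        return TestResult(0.0, 1.0, len(a) - 1, len(a))
    if np.std(d, ddof=1) == 0:
        raise UndefinedStatisticError("zero variance of paired differences")
    t, p = sps.ttest_rel(a, b)
    return TestResult(float(t), float(p), len(a) - 1, len(a))


def two_sample_compare(a, b) -> TestResult:
    """Two-sided two-sample t-test with pooled variance."""
    a, b = _as_arrays(a, b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return TestResult(0.0, 1.0, len(a) + len(b) - 2, len(a) + len(b))
        raise UndefinedStatisticError("zero variance in both samples")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), float(p), len(a) + len(b) - 2, len(a) + len(b))


def pearson(x, y) -> TestResult:
    """Pearson correlation with the t-distribution p-value."""
    x, y = _as_arrays(x, y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired inputs of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue), len(x) - 2, len(x))


def ks_compare(dist_a, dist_b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov comparison of empirical distributions."""
    a, b = _as_arrays(dist_a, dist_b)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("samples must be non-empty")
    res = sps.ks_2samp(a, b)
    return TestResult(float(res.statistic), float(res.pvalue), None, len(a) + len(b))


def bonferroni(p_list, m: int | None = None) -> list[float]:
    """Multiply p-values by ``m`` (default: list length) and cap at 1."""
    p = np.asarray(p_list, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"m ({m}) must be >= number of p-values ({len(p)})")
    return list(np.minimum(p * m, 1.0))


def two_way_anova(df: pd.DataFrame, value: str, factor_a: str, factor_b: str) -> pd.DataFrame:
    """Two-way ANOVA with interaction (delegated to statsmodels).

    Returns the ANOVA table with F statistics and p-values for the two
    main effects and their interaction.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = df.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [factor_a, factor_b, f"{factor_a}:{factor_b}", "Residual"]
    return table
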