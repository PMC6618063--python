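"""Evaluation statistics: least-squares regression with F-test, Bland-Altman.

The regression model is ``y = slope * x + intercept`` fitted by ordinary
least squares; the F statistic ``R^2 (n - 2) / (1 - R^2)`` on (1, n-2)
degrees of freedom tests for a significant linear relationship
(significance threshold 0.05).  Bland-Altman agreement reports the bias
(mean difference) and the limits of agreement ``bias +/- 1.96 SD`` of the
paired differences (sample SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

__all__ = [
    "RegressionResult",
    "BlandAltmanResult",
    "SIGNIFICANCE_LEVEL",
    "linear_regression",
    "bland_altman",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    lower_limit: float
    upper_limit: float
    n: int


def linear_regression(y, x) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` with an F-test on the slope.

    Raises
    ------
    ValueError
        On length mismatch, n < 3, or zero-variance x.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("x has zero variance")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (slope * x + intercept)
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    if r2 >= 1.0:
        f = np.inf
        p = 0.0
    else:
        f = r2 / ((1.0 - r2) / (n - 2))
        p = float(_stats.f.sf(f, 1, n - 2))
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        f_statistic=float(f),
        p_value=p,
        n=n,
    )


def bland_altman(a, b) -> BlandAltmanResult:
    """Agreement between paired measurements ``a`` and ``b``.

    Differences ``d = a - b``; bias = mean(d); limits of agreement =
    bias +/- 1.96 * SD(d) with the sample (n-1) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be paired 1-D arrays")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        lower_limit=bias - 1.96 * sd,
        upper_limit=bias + 1.96 * sd,
        n=a.size,
    )
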