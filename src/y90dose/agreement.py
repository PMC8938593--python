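"""Cross-modality statistics: regression with intervals, Bland-Altman, ANOVA.

The study convention for pairing CT- and PET-derived mean doses is fixed:
the CT mean dose is evaluated over the liver L, the PET mean dose over the
extended liver L_shell (the coarse, motion-smeared PET needs the margin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionSummary",
    "BlandAltmanResult",
    "AnovaResult",
    "linreg_ci",
    "bland_altman",
    "one_way_anova",
]


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r_squared: float
    slope_ci95: tuple[float, float]
    n: int


@dataclass
class BlandAltmanResult:
    """Paired-difference agreement: bias and 95% limits of agreement."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


def linreg_ci(x: list[float] | np.ndarray, y: list[float] | np.ndarray) -> RegressionSummary:
    """OLS of y on x with a t-based 95% CI on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has no variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return RegressionSummary(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        slope_ci95=(float(ci[1][0]), float(ci[1][1])),
        n=len(x),
    )


def bland_altman(a: list[float] | np.ndarray, b: list[float] | np.ndarray) -> BlandAltmanResult:
    """Bias (mean of a - b), SD of differences (n-1), limits bias +/- 1.96 SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("inputs must be paired (equal length)")
    if len(a) < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
                             n=len(a))


def one_way_anova(groups: list[list[float] | np.ndarray]) -> AnovaResult:
    """Standard one-way between/within decomposition."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*arrs)
    n_total = sum(len(g) for g in arrs)
    return AnovaResult(f=float(f), df_between=len(arrs) - 1,
                       df_within=n_total - len(arrs), p=float(p))
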