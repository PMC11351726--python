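"""Statistical comparisons for IVFC studies.

Pearson correlation with simple linear regression and its slope F-test
(velocity or concentration against vessel diameter), and unpaired
two-sided t-tests for per-timepoint group comparison of concentration
curves.  The t-test defaults to the Student (pooled-variance) form, the
conventional "unpaired t-test"; Welch is available via ``equal_var=False``.

For simple regression the slope F-statistic with (1, n-2) degrees of
freedom equals the square of the slope t-statistic, and its p-value equals
the two-sided Pearson p-value — the implementation maintains these
identities to floating-point accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    slope: float
    intercept: float
    F: float
    p_r: float
    p_F: float

    def to_dict(self) -> dict:
        return {
            "r": self.r, "n": self.n, "slope": self.slope,
            "intercept": self.intercept, "F": self.F,
            "p_r": self.p_r, "p_F": self.p_F,
        }


def pearson_with_regression(x, y) -> CorrelationResult:
    """Pearson r plus least-squares line and slope F-test.

    ``F = t_slope**2`` with (1, n-2) df; ``p_r == p_F`` (both from the t
    distribution with n-2 df).  Requires n >= 3 and nonzero variance in
    both variables.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateDataError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"need at least 3 points, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise DegenerateDataError("constant input has no defined correlation")
    sxy = float(xc @ yc)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    df = n - 2
    if abs(r) == 1.0:
        F = float("inf")
        p = 0.0
    else:
        t_slope = r * math.sqrt(df / (1.0 - r * r))
        F = t_slope ** 2
        p = 2.0 * float(sps.t.sf(abs(t_slope), df))
    return CorrelationResult(r=r, n=n, slope=slope, intercept=intercept,
                             F=F, p_r=p, p_F=p)


def unpaired_t_test(a, b, *, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; returns (t, p, df).

    Student (pooled variance, df = n_a + n_b - 2) by default, Welch with
    ``equal_var=False``.  Degenerate inputs are defined, not errors: zero
    pooled variance with equal means gives (0, 1); with unequal means the
    separation is infinite and p is reported as the smallest positive
    normal float.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("each group needs at least two observations")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_var:
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = float(na + nb - 2)
    if se == 0:
        if diff == 0:
            return 0.0, 1.0, df
        return math.copysign(float("inf"), diff), _TINY, df
    t = diff / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), max(p, _TINY), df


def timepoint_tests(
    timecourse_frame: pd.DataFrame,
    treated: str,
    control: str,
    value: str = "concentration_per_ml",
    *,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-timepoint unpaired t-tests between two groups of a time course.

    ``timecourse_frame`` is the tidy table with columns ``group``,
    ``time_min`` and ``value``.  Raw per-timepoint p-values are reported
    without multiplicity correction (the convention for annotating
    longitudinal curves point by point).
    """
    rows = []
    for t in sorted(timecourse_frame["time_min"].unique()):
        at_t = timecourse_frame[timecourse_frame["time_min"] == t]
        a = at_t.loc[at_t["group"] == treated, value].to_numpy()
        b = at_t.loc[at_t["group"] == control, value].to_numpy()
        tstat, p, df = unpaired_t_test(a, b, equal_var=equal_var)
        rows.append({"time_min": t, "t": tstat, "p": p, "df": df,
                     "n_treated": a.size, "n_control": b.size})
    return pd.DataFrame(rows)
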