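"""Simple cohort-level statistics: OLS regressions and Welch's t-test.

Thin, typed wrappers over scipy.stats that return the quantities the cohort
report tabulates.  Welch's (unequal-variance) t is used throughout — the
fractional degrees of freedom in the source study identify it — and reduces
to Student's t exactly when variances and group sizes are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = ["OlsFit", "WelchResult", "simple_ols", "welch_t"]


@dataclass(frozen=True)
class OlsFit:
    intercept: float
    slope: float
    r2: float
    se_slope: float
    pvalue: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class WelchResult:
    t_stat: float
    df: float
    pvalue: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return asdict(self)


def simple_ols(x, y) -> OlsFit:
    """Simple linear regression with a two-sided t-based slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope undefined")
    res = sps.linregress(x, y)
    return OlsFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r2=float(res.rvalue**2),
        se_slope=float(res.stderr),
        pvalue=float(res.pvalue),
        n=int(x.size),
    )


def welch_t(a, b) -> WelchResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df.

    When both groups have zero variance and equal means the statistic is
    undefined and reported as nan rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return WelchResult(
            t_stat=float("nan"), df=float("nan"), pvalue=float("nan"),
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            sd_a=0.0, sd_b=0.0, n_a=int(a.size), n_b=int(b.size),
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        pvalue=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
    )
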