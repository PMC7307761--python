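"""Six-sigma waiting-time diagnostics.

Process capability of an emergency department is judged against a single
upper specification limit (USL) on the door-to-physician waiting time —
30 minutes in the built-in case.  Under a normal model with mean ``mu`` and
standard deviation ``sigma``:

    Zu          = (USL - mu) / sigma          (short-term sigma level)
    Cps         = Zu / 3                      (one-sided capability index)
    P(error)    = P(wait > USL) = Phi(-Zu)
    PPM         = 1e6 * P(error)
    efficiency  = 1 - P(error)
    sigma_long  = Zu - 1.5                    (conventional 1.5-sigma shift)

Also provides individuals / moving-range (X-mR) control charts with the
standard constants 2.66 and 3.267.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CapabilityReport:
    usl: float
    mean: float
    sd: float
    zu: float
    cps: float
    p_error: float
    ppm: float
    efficiency: float
    sigma_short: float
    sigma_long: float
    normality_p: float | None = None
    normality_warning: bool = False
    normality_statistic: float | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "usl", "mean", "sd", "zu", "cps", "p_error", "ppm",
            "efficiency", "sigma_short", "sigma_long",
            "normality_p", "normality_warning", "normality_statistic")}


@dataclass(frozen=True)
class ControlChart:
    """Individuals chart plus its companion moving-range chart."""

    center: float
    ucl: float
    lcl: float
    mr_center: float
    mr_ucl: float
    mr_lcl: float
    out_of_control: tuple
    mr_out_of_control: tuple


def capability_metrics(mean: float, sd: float, usl: float) -> CapabilityReport:
    """Capability report from summary statistics under a normal model."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if usl <= 0:
        raise ValueError("usl must be > 0")
    zu = (usl - mean) / sd
    p_err = float(stats.norm.sf(zu))
    return CapabilityReport(
        usl=usl, mean=mean, sd=sd,
        zu=zu, cps=zu / 3.0,
        p_error=p_err, ppm=1e6 * p_err, efficiency=1.0 - p_err,
        sigma_short=zu, sigma_long=zu - 1.5,
    )


def normal_correlation_test(series) -> tuple[float, float]:
    """Correlation-type normality test (Ryan-Joiner / Shapiro-Francia kind).

    The statistic is the correlation between the order statistics and their
    normal scores (Blom plotting positions).  The p-value uses Royston's
    normal approximation for ln(1 - r**2), which stays well behaved at the
    sample sizes an operational-year waiting-time series reaches.
    """
    x = np.sort(np.asarray(series, dtype=float))
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    b = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    r = float(np.corrcoef(x, b)[0, 1])
    w = r * r
    g = math.log(max(1.0 - w, 1e-300))
    u, v = math.log(math.log(n)), math.log(n)
    mu = -1.2725 + 1.0521 * (u - v)
    sigma = 1.0308 - 0.26758 * (u + 2.0 / v)
    z = (g - mu) / sigma
    return r, float(stats.norm.sf(z))


#: backwards-compatible alias for the correlation-type normality check
ryan_joiner = normal_correlation_test


def capability_from_series(waits, usl: float) -> CapabilityReport:
    """Estimate mean/sd from data, check normality, and report capability.

    ``normality_warning`` is set when the correlation-type normality test
    rejects at the 5% level; the capability figures assume normality and
    should then be read with care.
    """
    x = np.asarray(waits, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = float(np.std(x, ddof=1))
    if sd <= 0:
        raise ValueError("series is constant; sd = 0")
    r, p = (normal_correlation_test(x) if x.size >= 5 else (None, None))
    rep = capability_metrics(float(np.mean(x)), sd, usl)
    return CapabilityReport(
        **{**rep.to_dict(),
           "normality_p": p,
           "normality_warning": p is not None and p < 0.05,
           "normality_statistic": r})


def individuals_chart(series) -> ControlChart:
    """X-mR chart for individual observations.

    Limits: center +/- 2.66 * mean moving range for the individuals chart;
    [0, 3.267 * mean moving range] for the moving-range chart.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    mr = np.abs(np.diff(x))
    mr_bar = float(np.mean(mr))
    center = float(np.mean(x))
    ucl = center + 2.66 * mr_bar
    lcl = center - 2.66 * mr_bar
    mr_ucl = 3.267 * mr_bar
    ooc = tuple(int(i) for i in np.flatnonzero((x > ucl) | (x < lcl)))
    mr_ooc = tuple(int(i) + 1 for i in np.flatnonzero(mr > mr_ucl))
    return ControlChart(center=center, ucl=ucl, lcl=lcl,
                        mr_center=mr_bar, mr_ucl=mr_ucl, mr_lcl=0.0,
                        out_of_control=ooc, mr_out_of_control=mr_ooc)
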