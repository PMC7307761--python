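"""Simulation input analysis: randomness, homogeneity, goodness of fit,
and arrival-pipeline partitioning.

Before a stage time or interarrival series can drive the simulator it is
screened the way a simulation practitioner would: a runs test for serial
randomness, a Kruskal-Wallis test for sub-groups, a chi-squared
goodness-of-fit over candidate families, and — for arrivals — a partition
into the 21 weekday x time-slot pipelines with an across-cell
heterogeneity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import DistributionSpec
from .scenario import SLOTS, WEEKDAYS

ALPHA = 0.05


@dataclass(frozen=True)
class RandomnessReport:
    variable: str
    runs: int                 # raw number of runs about the median
    k_statistic: float        # standardized statistic
    p_value: float
    random: bool              # at alpha = 0.05

    def to_dict(self) -> dict:
        return {"variable": self.variable, "runs": self.runs,
                "k_statistic": self.k_statistic, "p_value": self.p_value,
                "random": self.random}


@dataclass(frozen=True)
class FitResult:
    variable: str
    family: str
    params: dict
    statistic: float
    df: int
    p_value: float
    accepted: bool            # at alpha = 0.05

    def to_dict(self) -> dict:
        return {"variable": self.variable, "family": self.family,
                "params": dict(self.params), "statistic": self.statistic,
                "df": self.df, "p_value": self.p_value,
                "accepted": self.accepted}


@dataclass(frozen=True)
class HomogeneityReport:
    statistic: float
    p_value: float
    conclusion: str           # "Homogeneous" | "Heterogeneous"


def runs_test(series, variable: str = "series") -> RandomnessReport:
    """Runs-about-the-median test with the normal approximation.

    Observations equal to the median are dropped.  Two-sided p-value; the
    null of serial randomness is retained when p >= 0.05.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations")
    med = np.median(x)
    signs = x[x != med] > med
    if signs.size == 0 or signs.all() or (~signs).all():
        raise ValueError("degenerate series: all values on one side of the median")
    n1 = int(signs.sum())
    n2 = int(signs.size - n1)
    runs = 1 + int(np.count_nonzero(signs[1:] != signs[:-1]))
    n = n1 + n2
    mean = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    z = (runs - mean) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    p = min(p, 1.0)
    return RandomnessReport(variable, runs, float(z), p, p >= ALPHA)


def homogeneity_test(groups) -> HomogeneityReport:
    """Kruskal-Wallis rank test across groups.

    "Homogeneous" when p >= 0.05 (no evidence of sub-groups), else
    "Heterogeneous".
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    stat, p = stats.kruskal(*groups)
    return HomogeneityReport(float(stat), float(p),
                             "Homogeneous" if p >= ALPHA else "Heterogeneous")


# -- goodness of fit --------------------------------------------------------

def _fit_family(x: np.ndarray, family: str):
    """Moment/ML estimates and a frozen scipy distribution for a family."""
    m = float(np.mean(x))
    v = float(np.var(x, ddof=1))
    if family == "exponential":
        return {"mean": m}, stats.expon(scale=m), 1
    if family == "gamma":
        shape = m * m / v
        scale = v / m
        return {"shape": shape, "scale": scale}, stats.gamma(shape, scale=scale), 2
    if family == "lognormal":
        s2 = math.log1p(v / (m * m))
        mu = math.log(m) - 0.5 * s2
        return ({"mu": mu, "sigma": math.sqrt(s2)},
                stats.lognorm(math.sqrt(s2), scale=math.exp(mu)), 2)
    if family == "uniform":
        hw = math.sqrt(3.0 * v)
        return ({"low": m - hw, "high": m + hw},
                stats.uniform(loc=m - hw, scale=2 * hw), 2)
    if family == "triangular":
        hw = math.sqrt(6.0 * v)
        return ({"left": m - hw, "mode": m, "right": m + hw},
                stats.triang(0.5, loc=m - hw, scale=2 * hw), 2)
    if family == "normal":
        sd = math.sqrt(v)
        return {"mean": m, "sd": sd}, stats.norm(m, sd), 2
    raise ValueError(f"unknown candidate family {family!r}")


def chi_squared_bins(n: int) -> int:
    """Equal-probability bin count: max(5, n // 50), capped at 30."""
    return min(30, max(5, n // 50))


def fit_distribution(series, candidates, variable: str = "series") -> list[FitResult]:
    """Chi-squared goodness of fit over candidate families, best first.

    Parameters are estimated by moment matching; the statistic uses
    equal-probability bins from the fitted CDF; df = bins - 1 - #params.
    Results are ranked by p-value descending; ``accepted`` at alpha = 0.05.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 30:
        raise ValueError("need at least 30 observations")
    if np.var(x) == 0:
        raise ValueError("degenerate (constant) series")
    if not candidates:
        raise ValueError("need at least one candidate family")
    n = x.size
    k = chi_squared_bins(n)
    results = []
    for fam in candidates:
        params, dist, n_par = _fit_family(x, fam)
        edges = dist.ppf(np.linspace(0.0, 1.0, k + 1))
        edges[0], edges[-1] = -np.inf, np.inf
        observed, _ = np.histogram(x, bins=edges)
        expected = n / k
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        df = max(1, k - 1 - n_par)
        p = float(stats.chi2.sf(chi2, df))
        results.append(FitResult(variable, fam, params, chi2, df, p, p >= ALPHA))
    results.sort(key=lambda r: -r.p_value)
    return results


# -- arrival partitioning ---------------------------------------------------

def slot_of_hour(hour: float) -> str:
    """Half-open 8-hour slots: [0,8) -> P1, [8,16) -> P2, [16,24) -> P3."""
    return SLOTS[int(hour) // 8]


@dataclass(frozen=True)
class ArrivalPartition:
    """21 weekday x slot cells of interarrival series plus the across-cell
    heterogeneity verdict (whether slot/weekday partitioning is warranted)."""

    cells: dict              # (weekday, slot) -> np.ndarray of gaps (minutes)
    counts: dict             # (weekday, slot) -> arrival count
    heterogeneity: HomogeneityReport | None

    @property
    def partition_warranted(self) -> bool:
        return (self.heterogeneity is not None
                and self.heterogeneity.conclusion == "Heterogeneous")


def partition_arrivals(timestamps, test: str = "kruskal") -> ArrivalPartition:
    """Assign calendar arrivals to the 21 weekday x slot pipelines.

    Interarrival gaps are computed between consecutive arrivals within the
    same contiguous (date, slot) block, then pooled by (weekday, slot).
    The across-cell test is Kruskal-Wallis by default (interarrivals are
    skewed); ``test="anova"`` uses the classical one-way F-test instead.
    """
    ts = pd.to_datetime(pd.Series(list(timestamps)))
    if ts.empty:
        raise ValueError("no timestamps")
    if not ts.is_monotonic_increasing:
        raise ValueError("timestamps must be sorted ascending")
    if test not in ("kruskal", "anova"):
        raise ValueError(f"unknown test {test!r}")
    wd = ts.dt.dayofweek.map(dict(enumerate(WEEKDAYS)))
    slot = ts.dt.hour.map(lambda h: slot_of_hour(h))
    counts: dict = {(w, s): 0 for w in WEEKDAYS for s in SLOTS}
    gaps: dict = {(w, s): [] for w in WEEKDAYS for s in SLOTS}
    block = list(zip(ts.dt.date, slot))
    for i in range(len(ts)):
        counts[(wd.iloc[i], slot.iloc[i])] += 1
        if i > 0 and block[i] == block[i - 1]:
            gap = (ts.iloc[i] - ts.iloc[i - 1]).total_seconds() / 60.0
            gaps[(wd.iloc[i], slot.iloc[i])].append(gap)
    cells = {k: np.asarray(v, dtype=float) for k, v in gaps.items()}
    nonempty = [v for v in cells.values() if v.size >= 2]
    het = None
    if len(nonempty) >= 2:
        if test == "kruskal":
            het = homogeneity_test(nonempty)
        else:
            stat, p = stats.f_oneway(*nonempty)
            het = HomogeneityReport(float(stat), float(p),
                                    "Homogeneous" if p >= ALPHA
                                    else "Heterogeneous")
    return ArrivalPartition(cells=cells, counts=counts, heterogeneity=het)
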