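"""Moment-matched service-time and interarrival distributions.

Every stochastic input to the simulator is described by a
:class:`DistributionSpec` — a family name plus a target mean and variance.
Parameters are recovered by moment matching, so a scenario document only
needs to state the two moments a practitioner can actually estimate from
hospital records.

Supported families: ``exponential``, ``gamma``, ``lognormal``,
``triangular`` (symmetric), ``uniform`` and ``deterministic``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

FAMILIES = (
    "exponential",
    "gamma",
    "lognormal",
    "triangular",
    "uniform",
    "deterministic",
)


class DistributionError(ValueError):
    """Raised for an unknown family or moments the family cannot attain."""


@dataclass(frozen=True)
class DistributionSpec:
    """A distribution family pinned down by its first two moments.

    ``mean`` is in minutes; ``var`` in minutes².  For ``exponential`` the
    variance is implied (mean²) and any supplied value is ignored; for
    ``deterministic`` it must be 0.
    """

    family: str
    mean: float
    var: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DistributionError(f"unknown distribution family: {self.family!r}")
        if self.mean < 0:
            raise DistributionError(f"negative mean: {self.mean}")
        if self.var < 0:
            raise DistributionError(f"negative variance: {self.var}")
        if self.family in ("gamma", "lognormal") and self.mean > 0 and self.var <= 0:
            raise DistributionError(f"{self.family} requires a positive variance")
        if self.family in ("triangular", "uniform") and self.var > 0:
            # support must stay nonnegative: mean - halfwidth >= 0
            hw = self._halfwidth()
            if self.mean - hw < -1e-9:
                raise DistributionError(
                    f"{self.family}(mean={self.mean}, var={self.var}) "
                    "would have negative support"
                )

    def _halfwidth(self) -> float:
        if self.family == "triangular":
            return math.sqrt(6.0 * self.var)
        return math.sqrt(3.0 * self.var)

    @property
    def variance(self) -> float:
        """Variance actually realised by the matched distribution."""
        if self.family == "exponential":
            return self.mean**2
        if self.family == "deterministic":
            return 0.0
        return self.var

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the matched distribution (scalar when ``size`` is None)."""
        m, v = self.mean, self.var
        fam = self.family
        if fam == "deterministic" or m == 0.0:
            return np.full(size, m) if size is not None else m
        if fam == "exponential":
            return rng.exponential(m, size)
        if fam == "gamma":
            shape = m * m / v
            scale = v / m
            return rng.gamma(shape, scale, size)
        if fam == "lognormal":
            s2 = math.log1p(v / (m * m))
            mu = math.log(m) - 0.5 * s2
            return rng.lognormal(mu, math.sqrt(s2), size)
        if fam == "triangular":
            hw = self._halfwidth()
            if hw == 0:
                return np.full(size, m) if size is not None else m
            return rng.triangular(m - hw, m, m + hw, size)
        if fam == "uniform":
            hw = self._halfwidth()
            return rng.uniform(m - hw, m + hw, size)
        raise DistributionError(fam)  # pragma: no cover

    # --- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = {"family": self.family, "mean": self.mean}
        if self.family not in ("exponential", "deterministic"):
            d["var"] = self.var
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        return cls(
            family=str(d["family"]),
            mean=float(d["mean"]),
            var=float(d.get("var", 0.0)),
        )
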