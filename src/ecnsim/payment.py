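"""Collateral payment settlement for patient transfers.

When a triage-4/5 patient covered by insurer ``i`` (agreed unit utility
``M_i`` USD per admission) is transferred, the destination node receives

    max( floor(arrangement),  M_i * (1 + r) / (1 + gamma + theta) )

and the origin node the remainder, so the two shares always sum to M_i.
``r`` is the correlation between the destination's waiting time and the
number of transferred admissions it receives — nodes whose timeliness
degrades from collaborating are compensated.  ``gamma`` and ``theta`` are
the population shares of triage-4 and triage-5 admissions; the arrangement
(A, B or C, each with its own floor) is fixed by the destination node.
When origin and destination coincide the treating node simply receives M.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .scenario import NetworkScenario

ARRANGEMENTS = ("A", "B", "C")


class SettlementError(ValueError):
    """Settlement attempted for an insurer without an agreed unit utility."""


class DegenerateSeriesWarning(UserWarning):
    """A zero-variance series makes the correlation undefined; 0 is used."""


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (ledger-style), e.g. 2.5 -> 3, -2.5 -> -3."""
    q = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * q + 0.5), x) / q


@dataclass(frozen=True)
class SettlementRule:
    """All parameters needed to settle admissions in one network."""

    gamma: float
    theta: float
    floors: dict                     # arrangement -> USD
    arrangement_rule: dict           # destination node -> arrangement
    M: dict                          # insurer -> USD
    denominator: str = "sum"         # "sum": 1+gamma+theta; "product": 1+gamma*theta

    @classmethod
    def from_scenario(cls, scenario: NetworkScenario,
                      denominator: str = "sum") -> "SettlementRule":
        p = scenario.payment
        return cls(gamma=p.gamma, theta=p.theta, floors=dict(p.floors),
                   arrangement_rule=dict(p.arrangement_rule),
                   M=scenario.unit_utilities(), denominator=denominator)

    @property
    def denom(self) -> float:
        if self.denominator == "sum":
            return 1.0 + self.gamma + self.theta
        if self.denominator == "product":
            return 1.0 + self.gamma * self.theta
        raise ValueError(f"unknown denominator mode {self.denominator!r}")


@dataclass(frozen=True)
class PaymentSplit:
    insurer: str
    M: float
    r: float
    arrangement: str | None          # None for a same-node admission
    destination_share: float
    origin_share: float


@dataclass(frozen=True)
class CoalitionRow:
    insurer: str
    nap: int                         # admissions transferred in this direction
    r: float
    per_admission_destination: float
    per_admission_origin: float
    origin_total: float              # exact, unrounded USD
    destination_total: float


@dataclass(frozen=True)
class CoalitionStatement:
    """Per-direction settlement ledger: one row per insurer plus totals."""

    origin: str
    destination: str
    rows: tuple

    @property
    def origin_total(self) -> float:
        return sum(r.origin_total for r in self.rows)

    @property
    def destination_total(self) -> float:
        return sum(r.destination_total for r in self.rows)

    def rounded_rows(self) -> list[dict]:
        """Rows with USD totals rounded to the nearest dollar for reporting."""
        return [{
            "insurer": r.insurer, "nap": r.nap, "r": r.r,
            "origin_total": round_half_away(r.origin_total),
            "destination_total": round_half_away(r.destination_total),
        } for r in self.rows]


def destination_share(M: float, r: float, arrangement: str,
                      rule: SettlementRule) -> float:
    """Per-admission USD received by the destination node."""
    if arrangement not in rule.floors:
        raise ValueError(f"unknown arrangement {arrangement!r}")
    if r < 0:
        raise ValueError("r must be >= 0")
    return max(rule.floors[arrangement], M * (1.0 + r) / rule.denom)


def settle_admission(insurer: str, origin: str, destination: str,
                     r: float, rule: SettlementRule) -> PaymentSplit:
    """Split one admission's unit utility between origin and destination."""
    try:
        M = rule.M[insurer]
    except KeyError:
        raise SettlementError(
            f"insurer {insurer!r} has no agreed unit utility") from None
    if origin == destination:
        return PaymentSplit(insurer, M, r, None,
                            destination_share=M, origin_share=0.0)
    try:
        arrangement = rule.arrangement_rule[destination]
    except KeyError:
        raise SettlementError(
            f"no payment arrangement for destination {destination!r}") from None
    dest = destination_share(M, r, arrangement, rule)
    return PaymentSplit(insurer, M, r, arrangement,
                        destination_share=dest, origin_share=M - dest)


def estimate_r(destination_wait_by_period, transferred_admissions_by_period
               ) -> float:
    """Pearson correlation between a destination's per-period waiting time
    and the transferred admissions it received, clamped to [0, 1].

    A zero-variance series leaves the correlation undefined: 0 is returned
    with a :class:`DegenerateSeriesWarning`.
    """
    w = np.asarray(destination_wait_by_period, dtype=float)
    n = np.asarray(transferred_admissions_by_period, dtype=float)
    if w.shape != n.shape:
        raise ValueError("series must have equal length")
    if w.size < 3:
        raise ValueError("need at least 3 periods")
    if np.std(w) == 0.0 or np.std(n) == 0.0:
        warnings.warn("zero-variance series; r set to 0",
                      DegenerateSeriesWarning, stacklevel=2)
        return 0.0
    r = float(np.corrcoef(w, n)[0, 1])
    return min(1.0, max(0.0, r))


def settle_coalition(origin: str, destination: str, ledger: dict,
                     r_by_insurer: dict, rule: SettlementRule
                     ) -> CoalitionStatement:
    """Settle one transfer direction.

    ``ledger`` maps insurer -> admissions count (nap_i); ``r_by_insurer``
    maps insurer -> correlation.  Totals are kept exact internally;
    :meth:`CoalitionStatement.rounded_rows` gives the nearest-dollar view.
    """
    rows = []
    for insurer in ledger:
        nap = int(ledger[insurer])
        if nap < 0:
            raise ValueError(f"negative admission count for {insurer!r}")
        r = float(r_by_insurer.get(insurer, 0.0))
        split = settle_admission(insurer, origin, destination, r, rule)
        rows.append(CoalitionRow(
            insurer=insurer, nap=nap, r=r,
            per_admission_destination=split.destination_share,
            per_admission_origin=split.origin_share,
            origin_total=nap * split.origin_share,
            destination_total=nap * split.destination_share,
        ))
    return CoalitionStatement(origin, destination, tuple(rows))


def network_profits(statements, same_node_admissions: dict,
                    rule: SettlementRule) -> dict:
    """Total USD accruing to each node over a set of coalition statements.

    ``same_node_admissions`` maps node -> {insurer -> count} for patients
    treated where they arrived (the node receives M in full for each).
    """
    seen = set()
    profits: dict = {}
    for st in statements:
        key = (st.origin, st.destination)
        if key in seen:
            raise ValueError(f"duplicate settlement direction {key}")
        seen.add(key)
        profits[st.origin] = profits.get(st.origin, 0.0) + st.origin_total
        profits[st.destination] = (profits.get(st.destination, 0.0)
                                   + st.destination_total)
    for node, by_insurer in same_node_admissions.items():
        for insurer, count in by_insurer.items():
            try:
                M = rule.M[insurer]
            except KeyError:
                raise SettlementError(
                    f"insurer {insurer!r} has no agreed unit utility") from None
            profits[node] = profits.get(node, 0.0) + int(count) * M
    return profits
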