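"""Failure mode and effects analysis (FMEA) scoring for network risks.

Each failure mode is rated 1-10 on severity (S), frequency (F) and
detection difficulty (D); the risk priority number is RPN = S * F * D.
Risks with RPN > 125 are prioritised: "double-star" when severity is also
high (S >= 8), "single-star" otherwise.  (The high-severity band is stated
as 8-10 and the low band as below 7; S = 7 is mapped to single-star.)
"""

from __future__ import annotations

from dataclasses import dataclass

RPN_THRESHOLD = 125
SEVERITY_CRITICAL = 8


@dataclass(frozen=True)
class RiskItem:
    label: str
    severity: int
    frequency: int
    detection: int
    rpn: int
    flag: str  # "double-star" | "single-star" | "none"


def _check(name: str, v: int) -> int:
    v = int(v)
    if not 1 <= v <= 10:
        raise ValueError(f"{name} must be in 1..10, got {v}")
    return v


def score_risk(label: str, severity: int, frequency: int,
               detection: int) -> RiskItem:
    s = _check("severity", severity)
    f = _check("frequency", frequency)
    d = _check("detection", detection)
    rpn = s * f * d
    if rpn > RPN_THRESHOLD:
        flag = "double-star" if s >= SEVERITY_CRITICAL else "single-star"
    else:
        flag = "none"
    return RiskItem(label, s, f, d, rpn, flag)


def score_risks(items) -> list[RiskItem]:
    """Score an iterable of (label, S, F, D) and sort by priority.

    Order: RPN descending, then severity descending, then label — stable
    and deterministic for any input permutation.
    """
    scored = [score_risk(*it) for it in items]
    scored.sort(key=lambda r: (-r.rpn, -r.severity, r.label))
    return scored
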