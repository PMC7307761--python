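"""Network transfer rules: whether and where to send a low-acuity patient.

Only triage-4/5 (low-risk) patients may be transferred, and only between
nodes that both hold an agreement with the patient's insurer; uncovered
patients are always treated where they arrived (no patient dumping).  A
patient moves when some destination's expected wait plus the transfer time
beats the wait offered at the origin; among several alternatives the
lowest sum wins, ties broken by lexicographically smallest node id.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scenario import NetworkScenario, ScenarioReferenceError

TRANSFER_ELIGIBLE_TRIAGE = frozenset({4, 5})


@dataclass(frozen=True)
class TransferDecision:
    patient_id: object
    origin: str
    verdict: str                     # "stay" | "transfer"
    destination: str | None
    candidate_scores: dict           # node -> expected wait + transfer time
    origin_expected_wait: float


def eligible_destinations(triage_level: int, insurer: str, origin: str,
                          scenario: NetworkScenario) -> list:
    """ED-enabled nodes (other than the origin) the patient may move to.

    Empty for triage 1-3, and for patients whose insurer is outside the
    roster (special-regime or uncovered — they stay at the origin).  Both
    ends of a transfer must hold an agreement with the patient's insurer.
    """
    if triage_level not in TRANSFER_ELIGIBLE_TRIAGE:
        return []
    if insurer not in scenario.roster:
        return []  # no agreement exists; never dumped to another node
    origin_node = scenario.node(origin)
    if insurer not in origin_node.insurers:
        return []
    return [n.id for n in scenario.ed_nodes()
            if n.id != origin and insurer in n.insurers]


def queue_state_estimate(n_ahead: int, mean_pre_physician_service: float,
                         effective_servers: int) -> float:
    """Expected door-to-physician wait for a newly arriving patient.

    Default estimator: patients ahead at-or-above the arriving priority
    (queued or in pre-physician service) times the mean pre-physician
    service time, divided by the effective number of servers.
    """
    if effective_servers < 1:
        raise ValueError("effective_servers must be >= 1")
    if n_ahead < 0:
        raise ValueError("n_ahead must be >= 0")
    return n_ahead * mean_pre_physician_service / effective_servers


def planning_estimates(scenario: NetworkScenario,
                       which: str = "post_lss") -> dict:
    """Static per-node expected waits for planning mode.

    ``which="post_lss"`` uses each node's post-improvement mean waiting
    time (falling back to baseline where no improvement project ran);
    ``which="baseline"`` uses the pre-improvement means.
    """
    est = {}
    for n in scenario.nodes:
        if which == "post_lss":
            m = (n.post_lss_wait_mean if n.post_lss_wait_mean is not None
                 else n.baseline_wait_mean)
        elif which == "baseline":
            m = n.baseline_wait_mean
        else:
            raise ValueError(f"unknown estimate table {which!r}")
        est[n.id] = float(m)
    return est


def select_destination(patient_id, origin: str, candidates, estimates: dict,
                       transfer_times, slot: str | None = None
                       ) -> TransferDecision:
    """Score candidates and apply the transfer inequality.

    Each candidate's score is its expected wait plus the origin->candidate
    transfer time; the patient transfers iff the best score is strictly
    below the origin's expected wait.  Deterministic tie-break: lowest
    node id.  ``transfer_times`` is a TransferTimeMatrix, or a mapping
    slot -> matrix together with ``slot``.
    """
    if isinstance(transfer_times, dict):
        if slot is None:
            raise ValueError("slot required with a per-slot matrix mapping")
        transfer_times = transfer_times[slot]
    if origin not in estimates:
        raise ScenarioReferenceError(f"no wait estimate for origin {origin!r}")
    origin_wait = float(estimates[origin])
    scores = {}
    for c in candidates:
        if c not in estimates:
            raise ScenarioReferenceError(f"no wait estimate for {c!r}")
        scores[c] = float(estimates[c]) + transfer_times.time(origin, c)
    if scores:
        best = min(sorted(scores), key=scores.__getitem__)
        if scores[best] < origin_wait:
            return TransferDecision(patient_id, origin, "transfer", best,
                                    scores, origin_wait)
    return TransferDecision(patient_id, origin, "stay", None,
                            scores, origin_wait)


class TransferPolicy:
    """Transfer rules bound to a scenario, usable inside the simulator.

    ``estimator`` selects the expected-wait source: "dynamic" queries live
    queue state at the decision epoch; "planning" uses the static per-node
    mean table (desk planning with published waits).
    """

    def __init__(self, scenario: NetworkScenario, estimator: str = "dynamic",
                 planning_table: dict | None = None,
                 allow_chains: bool = False):
        self.scenario = scenario
        if estimator not in ("dynamic", "planning"):
            raise ValueError(f"unknown estimator {estimator!r}")
        self.estimator = estimator
        self.planning_table = (planning_table if planning_table is not None
                               else planning_estimates(scenario))
        #: whether a transferred patient may be transferred again; the
        #: default forbids chains (one transfer per patient).
        self.allow_chains = allow_chains

    def decide(self, patient_id, triage_level: int, insurer: str,
               origin: str, slot: str, dynamic_estimates: dict | None = None,
               already_transferred: bool = False) -> TransferDecision:
        if already_transferred and not self.allow_chains:
            return TransferDecision(patient_id, origin, "stay", None, {}, 0.0)
        candidates = eligible_destinations(triage_level, insurer, origin,
                                           self.scenario)
        if not candidates:
            est = (dynamic_estimates or self.planning_table)
            return TransferDecision(patient_id, origin, "stay", None, {},
                                    float(est.get(origin, 0.0)))
        if self.estimator == "dynamic":
            if dynamic_estimates is None:
                raise ValueError("dynamic estimator needs live estimates")
            estimates = dynamic_estimates
        else:
            estimates = self.planning_table
        return select_destination(patient_id, origin, candidates, estimates,
                                  self.scenario.transfer_times, slot)
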