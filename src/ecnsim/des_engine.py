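"""Discrete-event simulation of patient flow through an emergency care
network.

Each node runs the stage sequence

    arrival -> triage -> (transfer decision) -> admission ->
    bed preparation -> nursing assistance -> physician assessment ->
    treatment -> departure

with priority queues at every stage (triage level 1 served first, FIFO
within a level).  Beds are seized at bed preparation and released at
departure; an arrival finding every bed occupied at its bed-request epoch
is counted as blocked but still queues.  With a transfer policy attached,
triage-4/5 patients may be routed to another node after triage; they
re-enter the destination at its admission stage (triage is not repeated)
after the slot-specific transfer time.

The event calendar is a binary heap keyed by (time, insertion order), so a
fixed seed yields a bitwise-identical patient log.  Statistics are
collected only for patients arriving after the warm-up period.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .scenario import (
    PRE_PHYSICIAN_STAGES,
    SLOTS,
    STAGES,
    WEEKDAYS,
    NetworkScenario,
)
from .transfer_policy import (
    TRANSFER_ELIGIBLE_TRIAGE,
    TransferPolicy,
    queue_state_estimate,
)

MINUTES_PER_DAY = 1440.0


def weekday_at(t: float) -> str:
    """Calendar weekday at simulation minute ``t`` (clock starts Mon 00:00)."""
    return WEEKDAYS[int(t // MINUTES_PER_DAY) % 7]


def slot_at(t: float) -> str:
    return SLOTS[int((t % MINUTES_PER_DAY) // 480.0)]


@dataclass
class PatientRecord:
    id: int
    node_of_arrival: str
    arrival_epoch: float
    triage_level: int
    insurer: str
    stage_start: dict = field(default_factory=dict)
    stage_end: dict = field(default_factory=dict)
    transferred_to: str | None = None
    treating_node: str = ""
    blocked_flag: bool = False
    departure_epoch: float | None = None

    @property
    def door_to_physician(self) -> float | None:
        """Minutes from arrival to the start of physician assessment."""
        start = self.stage_start.get("physician")
        return None if start is None else start - self.arrival_epoch

    @property
    def registration_to_physician(self) -> float | None:
        """Alternative metric: admission (registration) start to physician
        assessment start."""
        reg = self.stage_start.get("admission")
        start = self.stage_start.get("physician")
        return None if reg is None or start is None else start - reg


@dataclass
class ReplicationResult:
    horizon_days: float
    warmup_days: float
    seed: int
    wait_mean: dict                  # node -> mean door-to-physician (min)
    wait_var: dict                   # node -> sample variance
    wait_count: dict                 # node -> patients counted
    bed_occupancy: dict              # node -> time-average busy fraction
    blocking_probability: dict       # node -> blocked / bed requests
    transfer_counts: dict            # (origin, destination, insurer) -> count
    blocking_by_day: list            # network blocking fraction per day
    arrivals: int
    departures: int
    in_system_at_end: int
    patients: list                   # PatientRecords (post-warmup arrivals)

    def network_wait_mean(self) -> float:
        tot = sum(self.wait_count.values())
        if tot == 0:
            return float("nan")
        return sum(self.wait_mean[n] * self.wait_count[n]
                   for n in self.wait_mean if self.wait_count[n]) / tot


@dataclass(frozen=True)
class SummaryStats:
    n_reps: int
    mean: float                      # mean of per-replication network means
    half_width: float                # t-based CI half width
    confidence: float
    rep_means: tuple
    per_node_mean: dict
    per_node_half_width: dict


@dataclass(frozen=True)
class TestReport:
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


class ConfigurationError(ValueError):
    """The scenario cannot be simulated as configured."""


class _StageRes:
    __slots__ = ("servers", "busy", "queue")

    def __init__(self, servers: int):
        self.servers = servers
        self.busy = 0
        self.queue: list = []  # heap of (priority, seq, patient)


class _NodeState:
    def __init__(self, spec, warm: float):
        self.spec = spec
        self.stages = {st: _StageRes(spec.stage_servers.get(st, 1))
                       for st in STAGES}
        self.bed_cap = spec.beds or 0
        self.bed_busy = 0
        self.bed_queue: list = []
        self.occ_area = 0.0
        self.occ_last_t = warm
        self.bed_requests = 0
        self.blocked = 0
        # patients past triage but not yet in physician assessment,
        # counted per triage level: drives the dynamic wait estimator
        self.pre_phys = [0] * 6
        self.waits: list = []
        self.eff_servers = max(1, min(self.stages[s].servers
                                      for s in PRE_PHYSICIAN_STAGES))
        self.mean_pre_phys = (spec.pre_physician_mean()
                              if spec.stage_service else 0.0)

    def expected_wait(self, triage_level: int) -> float:
        n_ahead = sum(self.pre_phys[1:triage_level + 1])
        return queue_state_estimate(n_ahead, self.mean_pre_phys,
                                    self.eff_servers)


class _Engine:
    def __init__(self, scenario: NetworkScenario, policy, horizon: float,
                 warmup: float, seed: int):
        self.scenario = scenario
        self.policy = policy
        self.horizon = horizon
        self.warm = warmup
        self.events: list = []
        self.seq = 0
        self.now = 0.0
        ss = np.random.SeedSequence([int(seed), 0x51])
        nodes = scenario.ed_nodes()
        children = ss.spawn(2 * len(nodes))
        self.arr_rng = {n.id: np.random.default_rng(children[2 * i])
                        for i, n in enumerate(nodes)}
        self.svc_rng = {n.id: np.random.default_rng(children[2 * i + 1])
                        for i, n in enumerate(nodes)}
        self.state = {n.id: _NodeState(n, warmup) for n in nodes}
        for n in nodes:
            for st in STAGES:
                if st not in n.stage_service:
                    raise ConfigurationError(
                        f"node {n.id}: missing service distribution for {st}")
        weights = scenario.insurer_weights()
        self.insurer_labels = list(weights)
        self.insurer_cum = np.cumsum([weights[k] for k in self.insurer_labels])
        mix = scenario.triage_mix.probabilities
        self.triage_levels = sorted(mix)
        self.triage_cum = np.cumsum([mix[k] for k in self.triage_levels])
        self.pid = 0
        self.patients: list = []
        self.arrivals = 0
        self.departures = 0
        self.in_system = 0
        self.transfer_counts: dict = {}
        n_days = int(math.ceil(horizon / MINUTES_PER_DAY))
        self.day_blocked = [0] * n_days
        self.day_requests = [0] * n_days

    # -- event calendar -----------------------------------------------------
    def push(self, t: float, fn, *args) -> None:
        self.seq += 1
        heapq.heappush(self.events, (t, self.seq, fn, args))

    def run(self) -> None:
        for nid in self.state:
            self._schedule_arrival(nid, 0.0)
        while self.events:
            t, _, fn, args = heapq.heappop(self.events)
            if t > self.horizon:
                break
            self.now = t
            fn(*args)

    # -- arrivals -----------------------------------------------------------
    def _schedule_arrival(self, nid: str, t: float) -> None:
        node = self.state[nid].spec
        pmap = node.pipeline_map()
        spec = pmap[(weekday_at(t), slot_at(t))]
        if spec.mean <= 0 or math.isinf(spec.mean):
            # dead pipeline: re-probe at the next slot boundary
            nxt = (math.floor(t / 480.0) + 1) * 480.0
            if nxt < self.horizon:
                self.push(nxt, self._schedule_arrival, nid, nxt)
            return
        gap = float(spec.sample(self.arr_rng[nid]))
        t_next = t + gap
        if t_next <= self.horizon:
            self.push(t_next, self._arrive, nid)

    def _arrive(self, nid: str) -> None:
        t = self.now
        self._schedule_arrival(nid, t)
        rng = self.arr_rng[nid]
        triage = int(self.triage_levels[min(
            int(np.searchsorted(self.triage_cum, rng.random(),
                                side="right")),
            len(self.triage_levels) - 1)])
        insurer = self.insurer_labels[min(
            int(np.searchsorted(self.insurer_cum, rng.random(),
                                side="right")),
            len(self.insurer_labels) - 1)]
        self.pid += 1
        p = PatientRecord(self.pid, nid, t, triage, insurer,
                          treating_node=nid)
        self.arrivals += 1
        self.in_system += 1
        if t >= self.warm:
            self.patients.append(p)
        self._enter_stage(p, nid, "triage")

    # -- stage machinery ----------------------------------------------------
    def _enter_stage(self, p: PatientRecord, nid: str, stage: str) -> None:
        res = self.state[nid].stages[stage]
        if res.busy < res.servers:
            self._start_service(p, nid, stage)
        else:
            self.seq += 1
            heapq.heappush(res.queue, (p.triage_level, self.seq, p))

    def _start_service(self, p: PatientRecord, nid: str, stage: str) -> None:
        st = self.state[nid]
        st.stages[stage].busy += 1
        p.stage_start[stage] = self.now
        if stage == "physician":
            st.pre_phys[p.triage_level] -= 1
            if p.arrival_epoch >= self.warm:
                st.waits.append(self.now - p.arrival_epoch)
        dur = float(st.spec.stage_service[stage].sample(self.svc_rng[nid]))
        self.push(self.now + dur, self._end_service, p, nid, stage)

    def _end_service(self, p: PatientRecord, nid: str, stage: str) -> None:
        p.stage_end[stage] = self.now
        res = self.state[nid].stages[stage]
        res.busy -= 1
        if res.queue:
            _, _, nxt = heapq.heappop(res.queue)
            self._start_service(nxt, nid, stage)
        self._route(p, nid, stage)

    def _route(self, p: PatientRecord, nid: str, done: str) -> None:
        if done == "triage":
            self._after_triage(p, nid)
        elif done == "admission":
            self._request_bed(p, nid)
        elif done == "bed_preparation":
            self._enter_stage(p, nid, "nursing")
        elif done == "nursing":
            self._enter_stage(p, nid, "physician")
        elif done == "physician":
            self._enter_stage(p, nid, "treatment")
        elif done == "treatment":
            self._depart(p, nid)

    def _after_triage(self, p: PatientRecord, nid: str) -> None:
        if (self.policy is not None
                and p.triage_level in TRANSFER_ELIGIBLE_TRIAGE
                and p.transferred_to is None):
            est = {m: s.expected_wait(p.triage_level)
                   for m, s in self.state.items()}
            decision = self.policy.decide(
                p.id, p.triage_level, p.insurer, nid, slot_at(self.now),
                dynamic_estimates=est,
                already_transferred=p.transferred_to is not None)
            if decision.verdict == "transfer":
                dest = decision.destination
                tt = self.scenario.transfer_times[slot_at(self.now)]
                p.transferred_to = dest
                p.treating_node = dest
                key = (nid, dest, p.insurer)
                if p.arrival_epoch >= self.warm:
                    self.transfer_counts[key] = \
                        self.transfer_counts.get(key, 0) + 1
                self.push(self.now + tt.time(nid, dest),
                          self._arrive_transferred, p, dest)
                return
        st = self.state[nid]
        st.pre_phys[p.triage_level] += 1
        self._enter_stage(p, nid, "admission")

    def _arrive_transferred(self, p: PatientRecord, dest: str) -> None:
        st = self.state[dest]
        st.pre_phys[p.triage_level] += 1
        self._enter_stage(p, dest, "admission")

    # -- beds ---------------------------------------------------------------
    def _request_bed(self, p: PatientRecord, nid: str) -> None:
        st = self.state[nid]
        day = int(self.now // MINUTES_PER_DAY)
        if day < len(self.day_requests):
            self.day_requests[day] += 1
        if self.now >= self.warm:
            st.bed_requests += 1
        if st.bed_busy >= st.bed_cap:
            p.blocked_flag = True
            if day < len(self.day_blocked):
                self.day_blocked[day] += 1
            if self.now >= self.warm:
                st.blocked += 1
            self.seq += 1
            heapq.heappush(st.bed_queue, (p.triage_level, self.seq, p))
        else:
            self._seize_bed(p, nid)

    def _occ_update(self, st: _NodeState) -> None:
        t = min(self.now, self.horizon)
        if t > st.occ_last_t:
            st.occ_area += st.bed_busy * (t - st.occ_last_t)
            st.occ_last_t = t

    def _seize_bed(self, p: PatientRecord, nid: str) -> None:
        st = self.state[nid]
        self._occ_update(st)
        st.bed_busy += 1
        self._enter_stage(p, nid, "bed_preparation")

    def _depart(self, p: PatientRecord, nid: str) -> None:
        st = self.state[nid]
        self._occ_update(st)
        st.bed_busy -= 1
        p.departure_epoch = self.now
        self.in_system -= 1
        self.departures += 1
        if st.bed_queue:
            _, _, nxt = heapq.heappop(st.bed_queue)
            self._seize_bed(nxt, nid)

    # -- results ------------------------------------------------------------
    def result(self) -> ReplicationResult:
        self.now = self.horizon
        wait_mean, wait_var, wait_count = {}, {}, {}
        occupancy, blocking = {}, {}
        span = self.horizon - self.warm
        for nid, st in self.state.items():
            self._occ_update(st)
            w = np.asarray(st.waits)
            wait_count[nid] = int(w.size)
            wait_mean[nid] = float(w.mean()) if w.size else float("nan")
            wait_var[nid] = (float(w.var(ddof=1)) if w.size > 1
                             else float("nan"))
            occupancy[nid] = (st.occ_area / (st.bed_cap * span)
                              if st.bed_cap and span > 0 else 0.0)
            blocking[nid] = (st.blocked / st.bed_requests
                             if st.bed_requests else 0.0)
        by_day = [(b / r if r else 0.0)
                  for b, r in zip(self.day_blocked, self.day_requests)]
        return ReplicationResult(
            horizon_days=self.horizon / MINUTES_PER_DAY,
            warmup_days=self.warm / MINUTES_PER_DAY,
            seed=-1,
            wait_mean=wait_mean, wait_var=wait_var, wait_count=wait_count,
            bed_occupancy=occupancy, blocking_probability=blocking,
            transfer_counts=dict(self.transfer_counts),
            blocking_by_day=by_day,
            arrivals=self.arrivals, departures=self.departures,
            in_system_at_end=self.in_system,
            patients=self.patients,
        )


def simulate(scenario: NetworkScenario, policy: TransferPolicy | None,
             horizon: float, warmup: float, seed: int) -> ReplicationResult:
    """Run one replication.

    ``horizon`` and ``warmup`` are in days; statistics cover patients whose
    arrival falls after the warm-up.  Deterministic for a fixed seed.
    """
    if warmup < 0 or horizon <= warmup:
        raise ValueError("need horizon > warmup >= 0 (days)")
    eng = _Engine(scenario, policy, horizon * MINUTES_PER_DAY,
                  warmup * MINUTES_PER_DAY, seed)
    eng.run()
    res = eng.result()
    res.seed = int(seed)
    return res


def run_replications(scenario: NetworkScenario, policy, n_reps: int,
                     horizon: float, warmup: float, base_seed: int,
                     confidence: float = 0.95) -> SummaryStats:
    """Independent replications with seeds spawned from ``base_seed``."""
    if n_reps < 2:
        raise ValueError("need at least 2 replications")
    ss = np.random.SeedSequence(int(base_seed))
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_reps)]
    reps = [simulate(scenario, policy, horizon, warmup, s) for s in seeds]
    rep_means = np.array([r.network_wait_mean() for r in reps])
    mean = float(np.nanmean(rep_means))
    hw = _half_width(rep_means, confidence)
    node_ids = [n.id for n in scenario.ed_nodes()]
    per_node_mean, per_node_hw = {}, {}
    for nid in node_ids:
        vals = np.array([r.wait_mean[nid] for r in reps])
        per_node_mean[nid] = float(np.nanmean(vals))
        per_node_hw[nid] = _half_width(vals, confidence)
    return SummaryStats(n_reps=n_reps, mean=mean, half_width=hw,
                        confidence=confidence,
                        rep_means=tuple(float(x) for x in rep_means),
                        per_node_mean=per_node_mean,
                        per_node_half_width=per_node_hw)


def _half_width(x: np.ndarray, confidence: float) -> float:
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    se = float(np.std(x, ddof=1)) / math.sqrt(x.size)
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, x.size - 1))
    return tcrit * se


def required_replications(presample_sd: float, half_width: float,
                          confidence: float = 0.95) -> int:
    """Replications needed for a target CI half width.

    ceil((z * sd / h)^2) with z the two-sided normal quantile; never fewer
    than 2.  Fed by a pre-sample (conventionally 10 runs) standard
    deviation of the per-replication means.
    """
    if presample_sd <= 0 or half_width <= 0:
        raise ValueError("presample_sd and half_width must be > 0")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    return max(2, math.ceil((z * presample_sd / half_width) ** 2))


def detect_warmup(blocking_by_period, tolerance: float,
                  window: int = 1) -> int:
    """Smallest index after which the moving-window change in blocking
    probability stays below ``tolerance``; the series length if the series
    never stabilises.

    ``window`` smooths the series with a trailing moving average before
    differencing (1 = raw successive differences).
    """
    s = np.asarray(blocking_by_period, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    if s.size < 2:
        return 0
    if window > 1:
        kernel = np.ones(window) / window
        s = np.convolve(s, kernel, mode="valid")
    diffs = np.abs(np.diff(s))
    # last index where the change still exceeds tolerance
    bad = np.flatnonzero(diffs > tolerance)
    if bad.size == 0:
        return 0
    n_orig = int(np.asarray(blocking_by_period, dtype=float).size)
    if int(bad[-1]) == diffs.size - 1:
        return n_orig  # still moving at the end: never stabilised
    return min(n_orig, int(bad[-1]) + 1 + (window - 1))


def validate_against_observed(per_replication_means,
                              observed_mean: float,
                              confidence: float = 0.95) -> TestReport:
    """One-sample t test of the replication means against the observed
    system mean, with the CI of the mean."""
    x = np.asarray(per_replication_means, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replication means")
    if np.std(x, ddof=1) == 0.0:
        equal = bool(np.all(x == observed_mean))
        m = float(x.mean())
        return TestReport(statistic=0.0 if equal else math.inf,
                          p_value=1.0 if equal else 0.0,
                          ci_low=m, ci_high=m, degenerate=True)
    t_stat, p = stats.ttest_1samp(x, observed_mean)
    hw = _half_width(x, confidence)
    m = float(x.mean())
    return TestReport(float(t_stat), float(p), m - hw, m + hw)


def compare_scenarios(waits_current, waits_proposed,
                      confidence: float = 0.95) -> TestReport:
    """Two-sample rank comparison of waiting times.

    Mann-Whitney U with a Hodges-Lehmann confidence interval for the
    location difference, reported as proposed - current (negative means
    the proposed network is faster).
    """
    a = np.asarray(waits_current, dtype=float)
    b = np.asarray(waits_proposed, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u, p = stats.mannwhitneyu(b, a, alternative="two-sided")
    diffs = np.sort((b[:, None] - a[None, :]).ravel())
    n1, n2 = a.size, b.size
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    mu = n1 * n2 / 2.0
    sd = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    k = int(math.floor(mu - z * sd))
    k = max(0, min(k, diffs.size - 1))
    lo = float(diffs[k])
    hi = float(diffs[diffs.size - 1 - k])
    return TestReport(float(u), float(p), lo, hi)
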