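"""Network scenario model, the built-in case-study fixture, and a seeded
synthetic-scenario generator.

A :class:`NetworkScenario` is the single input document every other module
consumes: the nodes of an emergency care network (hospitals and points of
care), their bed capacities and stage service processes, slot-specific
transfer-time matrices, the insurer roster with agreed per-admission unit
utilities, the payment parameters of the collateral settlement model, and
the triage-acuity mix of the patient population.

Scenarios load from YAML/JSON documents and round-trip exactly through
:func:`serialize` / :func:`load_scenario`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .distributions import DistributionSpec

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
SLOTS = ("P1", "P2", "P3")  # [00:00,08:00), [08:00,16:00), [16:00,24:00)
SLOT_MINUTES = 480.0
#: Patient-flow stages inside a node, in order. Beds are seized at
#: bed_preparation and released at departure (end of treatment).
STAGES = (
    "triage",
    "admission",
    "bed_preparation",
    "nursing",
    "physician",
    "treatment",
)
#: stages between triage completion and the start of physician assessment;
#: their combined service time drives the door-to-physician wait estimator.
PRE_PHYSICIAN_STAGES = ("admission", "bed_preparation", "nursing")

SEMESTER_DAYS = 182.0

#: default share of a day's arrivals falling in each 8-hour slot
#: (night / daytime / evening); overridable per scenario document.
DEFAULT_SLOT_WEIGHTS = {"P1": 0.18, "P2": 0.42, "P3": 0.40}
#: default weekday demand multipliers (mean 1 across the week).
DEFAULT_WEEKDAY_FACTORS = {
    "Mon": 1.10, "Tue": 1.00, "Wed": 0.95, "Thu": 0.95,
    "Fri": 1.00, "Sat": 1.05, "Sun": 0.95,
}


class ScenarioValidationError(ValueError):
    """A scenario document violates an invariant; ``fields`` lists offenders."""

    def __init__(self, fields: list[str]):
        self.fields = list(fields)
        super().__init__("scenario validation failed: " + "; ".join(self.fields))


class ScenarioReferenceError(ValueError):
    """A matrix or rule references a node id that does not exist."""


@dataclass(frozen=True)
class ArrivalPipeline:
    """Interarrival process for one (weekday, slot) cell of a node."""

    weekday: str
    slot: str
    interarrival: DistributionSpec

    def to_dict(self) -> dict:
        return {
            "weekday": self.weekday,
            "slot": self.slot,
            "interarrival": self.interarrival.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArrivalPipeline":
        return cls(d["weekday"], d["slot"],
                   DistributionSpec.from_dict(d["interarrival"]))


@dataclass
class NodeSpec:
    """One network node: a hospital or a point of care (POC).

    ``beds=None`` means the node has no emergency department yet — it
    accepts no arrivals and is never a transfer destination until enabled.
    Demand is expressed per semester (182 days); waits in minutes.
    """

    id: str
    node_class: str  # "hospital" | "poc"
    complexity_level: int
    beds: int | None
    insurers: frozenset
    demand_mean: float = 0.0
    demand_var: float = 0.0
    baseline_wait_mean: float = 0.0
    baseline_wait_var: float = 0.0
    post_lss_wait_mean: float | None = None
    post_lss_wait_var: float | None = None
    stage_servers: dict = field(default_factory=dict)
    stage_service: dict = field(default_factory=dict)
    pipelines: list = field(default_factory=list)

    @property
    def ed_enabled(self) -> bool:
        return self.beds is not None

    def pipeline_map(self) -> dict:
        return {(p.weekday, p.slot): p.interarrival for p in self.pipelines}

    def pre_physician_mean(self) -> float:
        """Mean total service time from triage completion to physician start."""
        return sum(self.stage_service[s].mean for s in PRE_PHYSICIAN_STAGES)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "node_class": self.node_class,
            "complexity_level": self.complexity_level,
            "beds": self.beds,
            "insurers": sorted(self.insurers),
            "demand_mean": self.demand_mean,
            "demand_var": self.demand_var,
            "baseline_wait_mean": self.baseline_wait_mean,
            "baseline_wait_var": self.baseline_wait_var,
            "post_lss_wait_mean": self.post_lss_wait_mean,
            "post_lss_wait_var": self.post_lss_wait_var,
            "stage_servers": dict(self.stage_servers),
            "stage_service": {k: v.to_dict() for k, v in self.stage_service.items()},
            "pipelines": [p.to_dict() for p in self.pipelines],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NodeSpec":
        return cls(
            id=str(d["id"]),
            node_class=str(d["node_class"]),
            complexity_level=int(d["complexity_level"]),
            beds=None if d.get("beds") is None else int(d["beds"]),
            insurers=frozenset(d.get("insurers", ())),
            demand_mean=float(d.get("demand_mean", 0.0)),
            demand_var=float(d.get("demand_var", 0.0)),
            baseline_wait_mean=float(d.get("baseline_wait_mean", 0.0)),
            baseline_wait_var=float(d.get("baseline_wait_var", 0.0)),
            post_lss_wait_mean=(None if d.get("post_lss_wait_mean") is None
                                else float(d["post_lss_wait_mean"])),
            post_lss_wait_var=(None if d.get("post_lss_wait_var") is None
                               else float(d["post_lss_wait_var"])),
            stage_servers={str(k): int(v)
                           for k, v in d.get("stage_servers", {}).items()},
            stage_service={str(k): DistributionSpec.from_dict(v)
                           for k, v in d.get("stage_service", {}).items()},
            pipelines=[ArrivalPipeline.from_dict(p)
                       for p in d.get("pipelines", ())],
        )


@dataclass
class TransferTimeMatrix:
    """Door-to-door inter-node transfer times (minutes) for one time slot.

    Diagonal entries are not applicable and never used; the matrix need not
    be symmetric (road direction matters).
    """

    slot: str
    minutes: dict  # origin -> {destination -> minutes}

    def time(self, origin: str, destination: str) -> float:
        try:
            row = self.minutes[origin]
        except KeyError:
            raise ScenarioReferenceError(f"unknown origin node {origin!r}")
        try:
            return row[destination]
        except KeyError:
            raise ScenarioReferenceError(f"unknown destination node {destination!r}")

    def __getitem__(self, pair) -> float:
        return self.time(*pair)

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.minutes)
        return pd.DataFrame(
            [[self.minutes[o].get(d, float("nan")) for d in ids] for o in ids],
            index=ids, columns=ids,
        )

    def to_dict(self) -> dict:
        return {"slot": self.slot,
                "minutes": {o: dict(row) for o, row in self.minutes.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "TransferTimeMatrix":
        return cls(d["slot"],
                   {o: {dst: float(t) for dst, t in row.items()}
                    for o, row in d["minutes"].items()})

    @classmethod
    def from_csv(cls, text_or_path, slot: str) -> "TransferTimeMatrix":
        """Read a square matrix with node-id header row and index column.

        Empty / NA cells are allowed on the diagonal only.
        """
        df = pd.read_csv(text_or_path, index_col=0)
        minutes = {}
        for o in df.index:
            minutes[str(o)] = {
                str(d): float(df.loc[o, d])
                for d in df.columns if str(d) != str(o) and pd.notna(df.loc[o, d])
            }
        return cls(slot, minutes)


@dataclass(frozen=True)
class InsurerRow:
    """One healthcare promotion company: affiliation count and agreed
    per-admission unit utility M (USD)."""

    insurer: str
    affiliated: int
    unit_utility_M: float

    def to_dict(self) -> dict:
        return {"insurer": self.insurer, "affiliated": self.affiliated,
                "unit_utility_M": self.unit_utility_M}


@dataclass
class PaymentParams:
    """Parameters of the collateral payment model.

    gamma / theta are the population shares of triage-4 and triage-5
    admissions; ``floors`` maps arrangement letter to the minimum USD the
    destination node receives per transferred admission;
    ``arrangement_rule`` maps each destination node to its arrangement.
    """

    gamma: float
    theta: float
    floors: dict
    arrangement_rule: dict

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "theta": self.theta,
                "floors": dict(self.floors),
                "arrangement_rule": dict(self.arrangement_rule)}

    @classmethod
    def from_dict(cls, d: dict) -> "PaymentParams":
        return cls(float(d["gamma"]), float(d["theta"]),
                   {str(k): float(v) for k, v in d["floors"].items()},
                   {str(k): str(v) for k, v in d["arrangement_rule"].items()})


@dataclass
class TriageMix:
    """Probabilities over triage acuity levels 1 (most urgent) to 5."""

    probabilities: dict  # level (int) -> probability

    def p(self, level: int) -> float:
        return self.probabilities.get(level, 0.0)

    def to_dict(self) -> dict:
        return {str(k): v for k, v in self.probabilities.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "TriageMix":
        return cls({int(k): float(v) for k, v in d.items()})


#: insurer label used for patients without social-security coverage; they
#: are always treated at the node of arrival (no patient dumping).
UNCOVERED = "UNCOVERED"
#: label for special-regime patients (state-covered outside the roster);
#: like uncovered patients they hold no transfer agreement.
SPECIAL_REGIME = "SPECIAL"


@dataclass
class NetworkScenario:
    """Complete description of an emergency care network."""

    nodes: list
    transfer_times: dict  # slot -> TransferTimeMatrix
    insurer_table: list  # list[InsurerRow]
    payment: PaymentParams
    triage_mix: TriageMix
    waiting_time_standard_USL: float = 30.0
    special_regime: int = 0
    uncovered: int = 0

    # -- lookups ------------------------------------------------------------
    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise ScenarioReferenceError(f"unknown node {node_id!r}")

    @property
    def node_ids(self) -> list:
        return [n.id for n in self.nodes]

    def ed_nodes(self) -> list:
        return [n for n in self.nodes if n.ed_enabled]

    def insurer(self, label: str) -> InsurerRow:
        for row in self.insurer_table:
            if row.insurer == label:
                return row
        raise ScenarioReferenceError(f"unknown insurer {label!r}")

    @property
    def roster(self) -> frozenset:
        return frozenset(r.insurer for r in self.insurer_table)

    def unit_utilities(self) -> dict:
        return {r.insurer: r.unit_utility_M for r in self.insurer_table}

    def total_population_with_access(self) -> int:
        """Affiliated + special-regime + uncovered patients the network serves."""
        return (sum(r.affiliated for r in self.insurer_table)
                + self.special_regime + self.uncovered)

    def insurer_weights(self) -> dict:
        """Sampling weights over insurer labels, including the special-regime
        and uncovered pseudo-labels (neither holds a transfer agreement)."""
        w = {r.insurer: float(r.affiliated) for r in self.insurer_table}
        if self.special_regime:
            w[SPECIAL_REGIME] = float(self.special_regime)
        if self.uncovered:
            w[UNCOVERED] = float(self.uncovered)
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}

    # -- validation ---------------------------------------------------------
    def validate(self) -> "NetworkScenario":
        errs: list[str] = []
        ids = self.node_ids
        if len(set(ids)) != len(ids):
            errs.append("nodes: duplicate node ids")
        roster = self.roster
        for n in self.nodes:
            tag = f"nodes[{n.id}]"
            if n.node_class not in ("hospital", "poc"):
                errs.append(f"{tag}.node_class: {n.node_class!r}")
            if n.beds is not None and n.beds < 1:
                errs.append(f"{tag}.beds: must be >= 1 when ED enabled")
            for fld in ("demand_mean", "demand_var",
                        "baseline_wait_mean", "baseline_wait_var"):
                if getattr(n, fld) < 0:
                    errs.append(f"{tag}.{fld}: negative")
            if not n.insurers <= roster:
                errs.append(f"{tag}.insurers: not a subset of the global roster")
            if n.ed_enabled:
                cells = {(p.weekday, p.slot) for p in n.pipelines}
                expected = {(w, s) for w in WEEKDAYS for s in SLOTS}
                if cells != expected or len(n.pipelines) != 21:
                    errs.append(f"{tag}.pipelines: need exactly the 21 "
                                "weekday x slot cells")
                for st in STAGES:
                    if st not in n.stage_service:
                        errs.append(f"{tag}.stage_service: missing stage {st}")
                    if n.stage_servers.get(st, 1) < 1:
                        errs.append(f"{tag}.stage_servers[{st}]: must be >= 1")
        for slot, mat in self.transfer_times.items():
            known = set(ids)
            for o, row in mat.minutes.items():
                if o not in known:
                    raise ScenarioReferenceError(
                        f"transfer_times[{slot}]: unknown origin {o!r}")
                for d, t in row.items():
                    if d not in known:
                        raise ScenarioReferenceError(
                            f"transfer_times[{slot}]: unknown destination {d!r}")
                    if o != d and t <= 0:
                        errs.append(f"transfer_times[{slot}][{o}->{d}]: "
                                    "off-diagonal must be > 0")
            missing = [i for i in ids if i not in mat.minutes]
            if missing:
                errs.append(f"transfer_times[{slot}]: missing rows {missing}")
        for slot in SLOTS:
            if slot not in self.transfer_times:
                errs.append(f"transfer_times: missing slot {slot}")
        for r in self.insurer_table:
            if r.affiliated < 0:
                errs.append(f"insurer_table[{r.insurer}].affiliated: negative")
            if r.unit_utility_M <= 0:
                errs.append(f"insurer_table[{r.insurer}].unit_utility_M: "
                            "must be > 0")
        p = self.payment
        if not (0.0 <= p.gamma and 0.0 <= p.theta and p.gamma + p.theta <= 1.0):
            errs.append("payment.gamma/theta: need 0 <= gamma, theta and "
                        "gamma + theta <= 1")
        for arr, f in p.floors.items():
            if f <= 0:
                errs.append(f"payment.floors[{arr}]: must be > 0")
        for nid in ids:
            arr = p.arrangement_rule.get(nid)
            if arr is None:
                errs.append(f"payment.arrangement_rule: missing destination {nid}")
            elif arr not in p.floors:
                errs.append(f"payment.arrangement_rule[{nid}]: "
                            f"unknown arrangement {arr!r}")
        tot = sum(self.triage_mix.probabilities.values())
        if abs(tot - 1.0) > 1e-9:
            errs.append(f"triage_mix: probabilities sum to {tot}, not 1")
        if self.waiting_time_standard_USL <= 0:
            errs.append("waiting_time_standard_USL: must be > 0")
        if errs:
            raise ScenarioValidationError(errs)
        return self

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [n.to_dict() for n in self.nodes],
            "transfer_times": {s: m.to_dict()
                               for s, m in self.transfer_times.items()},
            "insurer_table": [r.to_dict() for r in self.insurer_table],
            "payment": self.payment.to_dict(),
            "triage_mix": self.triage_mix.to_dict(),
            "waiting_time_standard_USL": self.waiting_time_standard_USL,
            "special_regime": self.special_regime,
            "uncovered": self.uncovered,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkScenario":
        try:
            return cls(
                nodes=[NodeSpec.from_dict(x) for x in d["nodes"]],
                transfer_times={str(s): TransferTimeMatrix.from_dict(m)
                                for s, m in d["transfer_times"].items()},
                insurer_table=[InsurerRow(str(r["insurer"]),
                                          int(r["affiliated"]),
                                          float(r["unit_utility_M"]))
                               for r in d["insurer_table"]],
                payment=PaymentParams.from_dict(d["payment"]),
                triage_mix=TriageMix.from_dict(d["triage_mix"]),
                waiting_time_standard_USL=float(
                    d.get("waiting_time_standard_USL", 30.0)),
                special_regime=int(d.get("special_regime", 0)),
                uncovered=int(d.get("uncovered", 0)),
            )
        except (KeyError, TypeError, ValueError) as e:
            if isinstance(e, (ScenarioValidationError, ScenarioReferenceError)):
                raise
            raise ScenarioValidationError([f"document structure: {e}"]) from e


def serialize(scenario: NetworkScenario) -> str:
    """YAML rendering of a scenario; inverse of :func:`load_scenario`."""
    return yaml.safe_dump(scenario.to_dict(), sort_keys=False)


def load_scenario(document) -> NetworkScenario:
    """Parse and validate a scenario from YAML/JSON text, a mapping, or a
    file-like object."""
    if isinstance(document, NetworkScenario):
        return document.validate()
    if hasattr(document, "read"):
        document = document.read()
    if isinstance(document, (str, bytes)):
        data = yaml.safe_load(document)
    else:
        data = document
    if not isinstance(data, dict):
        raise ScenarioValidationError(["document: not a mapping"])
    return NetworkScenario.from_dict(data).validate()


# ---------------------------------------------------------------------------
# Built-in case-study fixture: 2 hospitals + 8 POCs
# ---------------------------------------------------------------------------

_CASE_TRANSFER_AFTERNOON = {
    "H1":   {"H2": 11, "POC1": 6,  "POC2": 22, "POC3": 10, "POC4": 4,
             "POC5": 8,  "POC6": 14, "POC7": 13, "POC8": 14},
    "H2":   {"H1": 12, "POC1": 18, "POC2": 29, "POC3": 19, "POC4": 12,
             "POC5": 13, "POC6": 13, "POC7": 9,  "POC8": 25},
    "POC1": {"H1": 6,  "H2": 19, "POC2": 19, "POC3": 7,  "POC4": 10,
             "POC5": 11, "POC6": 16, "POC7": 19, "POC8": 12},
    "POC2": {"H1": 16, "H2": 27, "POC1": 11, "POC3": 10, "POC4": 20,
             "POC5": 20, "POC6": 20, "POC7": 25, "POC8": 22},
    "POC3": {"H1": 9,  "H2": 19, "POC1": 8,  "POC2": 14, "POC4": 13,
             "POC5": 16, "POC6": 23, "POC7": 22, "POC8": 18},
    "POC4": {"H1": 4,  "H2": 11, "POC1": 9,  "POC2": 25, "POC3": 11,
             "POC5": 10, "POC6": 13, "POC7": 12, "POC8": 18},
    "POC5": {"H1": 8,  "H2": 13, "POC1": 11, "POC2": 28, "POC3": 15,
             "POC4": 9,  "POC6": 12, "POC7": 13, "POC8": 17},
    "POC6": {"H1": 14, "H2": 14, "POC1": 18, "POC2": 35, "POC3": 24,
             "POC4": 15, "POC5": 11, "POC7": 8,  "POC8": 17},
    "POC7": {"H1": 14, "H2": 9,  "POC1": 19, "POC2": 32, "POC3": 20,
             "POC4": 12, "POC5": 15, "POC6": 6,  "POC8": 22},
    "POC8": {"H1": 14, "H2": 24, "POC1": 12, "POC2": 13, "POC3": 18,
             "POC4": 18, "POC5": 13, "POC6": 16, "POC7": 21},
}

# id, class, complexity, beds, demand mean/var (patients per semester),
# baseline wait mean/var, post-improvement wait mean/var (minutes)
_CASE_NODES = [
    ("H1",   "hospital", 1, 12, 10255.72, 36.71,   182.96, 10610.38, 69.90, 3305.3),
    ("H2",   "hospital", 3, 35, 65908.5,  41137.0, 3.71,   0.31,     3.71,  0.31),
    ("POC1", "poc",      2, 11, 11521.08, 55.26,   188.36, 9854.44,  126.03, 3361.0),
    ("POC2", "poc",      2, 13, 8775.5,   23.83,   177.32, 10530.05, 89.87, 2381.3),
    ("POC3", "poc",      2, 11, 8370.25,  20.94,   184.50, 11427.58, 103.10, 2671.1),
    ("POC4", "poc",      3, None, 0.0,    0.0,     0.0,    0.0,      126.98, 4656.9),
    ("POC5", "poc",      2, 14, 14060.76, 49.08,   173.68, 11170.08, 26.11, 153.74),
    ("POC6", "poc",      2, 11, 8339.89,  42.73,   190.02, 10269.51, 17.14, 26.18),
    ("POC7", "poc",      2, 12, 10260.61, 47.71,   182.07, 9795.49,  13.89, 21.25),
    ("POC8", "poc",      2, 11, 8355.67,  41.67,   187.15, 10519.84, 13.20, 23.99),
]

#: affiliation counts and agreed unit utilities per insurer. The S count is
#: derived: the source table's figure is garbled, so it is back-computed
#: from the printed roster total 1,229,996.
_CASE_INSURERS = [
    ("S", 247_680, 10.34),
    ("BU", 159_033, 4.91),
    ("MS", 371_274, 4.91),
    ("COM", 106_386, 4.91),
    ("COO", 252_736, 5.11),
    ("SV", 92_887, 9.97),
]
_CASE_SPECIAL_REGIME = 37_314
_CASE_UNCOVERED = 47_973

#: synthetic stage service processes for the case network. The case study's
#: fitted per-stage distributions were never published, so these are
#: documented stand-ins: lognormal with coefficient of variation 0.5 and
#: means typical of an urban emergency department.
_CASE_STAGE_MEANS = {
    "triage": 5.0,
    "admission": 5.0,
    "bed_preparation": 8.0,
    "nursing": 10.0,
    "physician": 12.0,
    "treatment": 45.0,
}
_CASE_STAGE_CV = 0.5

_CASE_TRIAGE_MIX = {1: 0.05, 2: 0.10, 3: 0.20, 4: 0.19, 5: 0.46}


def _stage_service_defaults() -> dict:
    return {
        st: DistributionSpec("lognormal", m, (_CASE_STAGE_CV * m) ** 2)
        for st, m in _CASE_STAGE_MEANS.items()
    }


def _size_stage_servers(demand_per_semester: float, stage_means: dict,
                        target_util: float = 0.8) -> dict:
    """Server counts keeping each stage's offered load below ``target_util``."""
    lam = demand_per_semester / SEMESTER_DAYS / 1440.0  # patients per minute
    return {st: max(1, math.ceil(lam * m / target_util))
            for st, m in stage_means.items()}


def build_pipelines(demand_per_semester: float,
                    slot_weights: dict | None = None,
                    weekday_factors: dict | None = None,
                    family: str = "exponential") -> list:
    """The 21 weekday x slot arrival pipelines implied by a semester demand.

    Expected arrivals in slot ``s`` of weekday ``d`` are
    ``demand/182 * f_d * w_s``; the pipeline's mean interarrival time is the
    slot length (480 min) divided by that count.
    """
    sw = dict(DEFAULT_SLOT_WEIGHTS if slot_weights is None else slot_weights)
    wf = dict(DEFAULT_WEEKDAY_FACTORS if weekday_factors is None
              else weekday_factors)
    daily = demand_per_semester / SEMESTER_DAYS
    out = []
    for wd in WEEKDAYS:
        for slot in SLOTS:
            n_slot = daily * wf[wd] * sw[slot]
            mean_ia = SLOT_MINUTES / n_slot if n_slot > 0 else float("inf")
            if math.isinf(mean_ia):
                spec = DistributionSpec("deterministic", 0.0)  # unused
            else:
                spec = DistributionSpec(family, mean_ia,
                                        mean_ia**2 if family != "exponential"
                                        else 0.0)
            out.append(ArrivalPipeline(wd, slot, spec))
    return out


def case_study_scenario() -> NetworkScenario:
    """The built-in two-hospital, eight-POC case network.

    Transfer times are the printed afternoon matrix, replicated to all three
    slots (per-slot overrides are supported in scenario documents); insurer
    utilities, payment floors/arrangements, gamma/theta, demand and waiting
    time statistics are the case study's printed values. POC4 arrives with
    its ED disabled (``beds=None``).
    """
    roster = frozenset(i for i, _, _ in _CASE_INSURERS)
    stage_service = _stage_service_defaults()
    nodes = []
    for (nid, ncls, lvl, beds, dmean, dvar, bwm, bwv, pwm, pwv) in _CASE_NODES:
        enabled = beds is not None
        nodes.append(NodeSpec(
            id=nid, node_class=ncls, complexity_level=lvl, beds=beds,
            insurers=roster,
            demand_mean=dmean, demand_var=dvar,
            baseline_wait_mean=bwm, baseline_wait_var=bwv,
            post_lss_wait_mean=pwm, post_lss_wait_var=pwv,
            stage_servers=(_size_stage_servers(dmean, _CASE_STAGE_MEANS)
                           if enabled else {}),
            stage_service=dict(stage_service) if enabled else {},
            pipelines=build_pipelines(dmean) if enabled else [],
        ))
    transfer = {
        slot: TransferTimeMatrix(slot, {o: dict(r)
                                        for o, r in _CASE_TRANSFER_AFTERNOON.items()})
        for slot in SLOTS
    }
    arrangement = {nid: ("C" if nid == "H1" else "A" if nid == "H2" else "B")
                   for nid, *_ in _CASE_NODES}
    scen = NetworkScenario(
        nodes=nodes,
        transfer_times=transfer,
        insurer_table=[InsurerRow(i, n, m) for i, n, m in _CASE_INSURERS],
        payment=PaymentParams(gamma=0.19, theta=0.46,
                              floors={"A": 3.92, "B": 3.50, "C": 4.50},
                              arrangement_rule=arrangement),
        triage_mix=TriageMix(dict(_CASE_TRIAGE_MIX)),
        waiting_time_standard_USL=30.0,
        special_regime=_CASE_SPECIAL_REGIME,
        uncovered=_CASE_UNCOVERED,
    )
    return scen.validate()


# ---------------------------------------------------------------------------
# Synthetic-scenario generator
# ---------------------------------------------------------------------------

_SERVICE_FAMILIES = ("gamma", "lognormal", "triangular", "uniform")


def generate_scenario(seed: int, n_hospitals: int, n_pocs: int,
                      demand_scale: float = 1.0) -> NetworkScenario:
    """A random but valid network scenario, deterministic for a fixed seed.

    Hospitals draw semester demand in the 30k-70k range and 20-40 beds;
    POCs 8k-15k and 8-15 beds. Each ED-enabled node gets 21 exponential
    arrival pipelines whose rates sum to its (scaled) semester demand, and
    per-stage service distributions from a documented family set with
    realistic minute-scale means. ``demand_scale`` multiplies every node's
    demand, halving mean interarrival times when doubled.
    """
    if n_hospitals < 1 or n_pocs < 1:
        raise ValueError("need at least one hospital and one POC")
    if demand_scale <= 0:
        raise ValueError("demand_scale must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEC0]))
    roster = [i for i, _, _ in _CASE_INSURERS]
    ids = [f"H{i+1}" for i in range(n_hospitals)] + \
          [f"POC{i+1}" for i in range(n_pocs)]
    # weekday factors: jitter around 1, renormalised to mean 1
    wf = 1.0 + rng.uniform(-0.15, 0.15, 7)
    wf = wf / wf.mean()
    weekday_factors = {w: float(f) for w, f in zip(WEEKDAYS, wf)}
    sw = rng.dirichlet([4.0, 9.0, 8.0])  # night light, day/evening heavy
    slot_weights = {s: float(w) for s, w in zip(SLOTS, sw)}

    nodes = []
    for nid in ids:
        hosp = nid.startswith("H")
        demand = float(rng.uniform(30_000, 70_000) if hosp
                       else rng.uniform(8_000, 15_000)) * demand_scale
        beds = int(rng.integers(20, 41) if hosp else rng.integers(8, 16))
        stage_means = {st: float(m * rng.uniform(0.7, 1.3))
                       for st, m in _CASE_STAGE_MEANS.items()}
        stage_service = {}
        # cv capped so bounded families keep nonnegative support
        cv_hi = {"triangular": 0.40, "uniform": 0.55}
        for st, m in stage_means.items():
            fam = str(rng.choice(_SERVICE_FAMILIES))
            cv = float(rng.uniform(0.20, cv_hi.get(fam, 0.55)))
            stage_service[st] = DistributionSpec(fam, m, (cv * m) ** 2)
        wait_mean = float(rng.uniform(5, 200))
        wait_var = float(rng.uniform(0.5, 60)) ** 2
        nodes.append(NodeSpec(
            id=nid, node_class="hospital" if hosp else "poc",
            complexity_level=int(rng.integers(1, 4)),
            beds=beds,
            insurers=frozenset(roster),
            demand_mean=demand,
            demand_var=float(rng.uniform(0.001, 0.01)) * demand**2 / 100,
            baseline_wait_mean=wait_mean, baseline_wait_var=wait_var,
            post_lss_wait_mean=wait_mean * float(rng.uniform(0.3, 0.9)),
            post_lss_wait_var=wait_var,
            stage_servers=_size_stage_servers(demand, stage_means),
            stage_service=stage_service,
            pipelines=build_pipelines(demand, slot_weights, weekday_factors),
        ))

    transfer = {}
    for slot in SLOTS:
        minutes = {}
        for o in ids:
            minutes[o] = {d: float(np.round(rng.uniform(4, 35), 1))
                          for d in ids if d != o}
        transfer[slot] = TransferTimeMatrix(slot, minutes)

    counts = rng.integers(50_000, 400_000, len(roster))
    insurer_table = [InsurerRow(lbl, int(c), float(np.round(rng.uniform(3.5, 11), 2)))
                     for lbl, c in zip(roster, counts)]
    arrangement = {nid: ("C" if nid == "H1" else "A" if nid.startswith("H")
                         else "B") for nid in ids}
    scen = NetworkScenario(
        nodes=nodes,
        transfer_times=transfer,
        insurer_table=insurer_table,
        payment=PaymentParams(0.19, 0.46,
                              {"A": 3.92, "B": 3.50, "C": 4.50}, arrangement),
        triage_mix=TriageMix(dict(_CASE_TRIAGE_MIX)),
        waiting_time_standard_USL=30.0,
        special_regime=int(rng.integers(10_000, 60_000)),
        uncovered=int(rng.integers(10_000, 60_000)),
    )
    return scen.validate()
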