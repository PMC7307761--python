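import numpy as np
import pytest

from ecnsim.distributions import DistributionSpec
from ecnsim.scenario import (
    SLOTS,
    STAGES,
    WEEKDAYS,
    ArrivalPipeline,
    InsurerRow,
    NetworkScenario,
    NodeSpec,
    PaymentParams,
    TransferTimeMatrix,
    TriageMix,
    case_study_scenario,
)

_OTHER_STAGES = tuple(s for s in STAGES if s != "physician")


def single_node_scenario(interarrival_mean: float = 10.0,
                         service_mean: float = 8.0,
                         servers: int = 1,
                         beds: int = 500,
                         interarrival_family: str = "exponential",
                         service_family: str = "exponential",
                         other_stage_mean: float = 0.0) -> NetworkScenario:
    """One-node network where only the physician stage takes time.

    With exponential arrivals and service this is an M/M/c queue on the
    physician stage, and door-to-physician equals the queue wait — the
    closed-form benchmark configuration.
    """
    ia_var = interarrival_mean**2 if interarrival_family != "exponential" else 0.0
    pipes = [ArrivalPipeline(w, s, DistributionSpec(interarrival_family,
                                                    interarrival_mean, ia_var))
             for w in WEEKDAYS for s in SLOTS]
    other = DistributionSpec("deterministic", other_stage_mean)
    sv_var = service_mean**2 if service_family != "exponential" else 0.0
    node = NodeSpec(
        id="N1", node_class="hospital", complexity_level=1, beds=beds,
        insurers=frozenset({"S"}),
        stage_servers={**{st: 9999 for st in _OTHER_STAGES},
                       "physician": servers},
        stage_service={**{st: other for st in _OTHER_STAGES},
                       "physician": DistributionSpec(service_family,
                                                     service_mean, sv_var)},
        pipelines=pipes,
    )
    return NetworkScenario(
        nodes=[node],
        transfer_times={s: TransferTimeMatrix(s, {"N1": {}}) for s in SLOTS},
        insurer_table=[InsurerRow("S", 100, 10.0)],
        payment=PaymentParams(0.19, 0.46,
                              {"A": 3.92, "B": 3.50, "C": 4.50}, {"N1": "B"}),
        triage_mix=TriageMix({3: 1.0}),
        waiting_time_standard_USL=30.0,
    ).validate()


def deterministic_node_scenario(interarrival_mean: float = 200.0,
                                stage_mean: float = 4.0) -> NetworkScenario:
    """Single node, deterministic everything, no queueing possible."""
    pipes = [ArrivalPipeline(w, s, DistributionSpec("deterministic",
                                                    interarrival_mean))
             for w in WEEKDAYS for s in SLOTS]
    svc = DistributionSpec("deterministic", stage_mean)
    node = NodeSpec(
        id="N1", node_class="poc", complexity_level=2, beds=50,
        insurers=frozenset({"S"}),
        stage_servers={st: 50 for st in STAGES},
        stage_service={st: svc for st in STAGES},
        pipelines=pipes,
    )
    return NetworkScenario(
        nodes=[node],
        transfer_times={s: TransferTimeMatrix(s, {"N1": {}}) for s in SLOTS},
        insurer_table=[InsurerRow("S", 100, 10.0)],
        payment=PaymentParams(0.19, 0.46,
                              {"A": 3.92, "B": 3.50, "C": 4.50}, {"N1": "B"}),
        triage_mix=TriageMix({3: 1.0}),
        waiting_time_standard_USL=30.0,
    ).validate()


@pytest.fixture(scope="session")
def case():
    return case_study_scenario()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240611)
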