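"""Simulation engine: flow correctness, determinism, statistics."""

import numpy as np
import pytest

from ecnsim.des_engine import (
    compare_scenarios,
    detect_warmup,
    required_replications,
    run_replications,
    simulate,
    validate_against_observed,
)
from ecnsim.distributions import DistributionSpec
from ecnsim.scenario import STAGES, ArrivalPipeline, SLOTS, WEEKDAYS
from ecnsim.transfer_policy import TransferPolicy

from conftest import deterministic_node_scenario, single_node_scenario


def _patient_key(p):
    return (p.id, p.node_of_arrival, p.arrival_epoch, p.triage_level,
            p.insurer, tuple(sorted(p.stage_start.items())),
            tuple(sorted(p.stage_end.items())), p.transferred_to,
            p.blocked_flag, p.departure_epoch)


class TestFlow:
    def test_zero_arrival_rate_produces_nothing(self):
        scen = single_node_scenario()
        dead = [ArrivalPipeline(w, s, DistributionSpec("deterministic", 0.0))
                for w in WEEKDAYS for s in SLOTS]
        scen.nodes[0].pipelines = dead
        res = simulate(scen, None, horizon=2, warmup=0, seed=1)
        assert res.patients == [] and res.arrivals == 0
        assert res.bed_occupancy["N1"] == 0.0

    def test_lone_patient_wait_is_sum_of_upstream_stages(self):
        # deterministic stages, ample servers: door-to-physician is exactly
        # triage + admission + bed-preparation + nursing service time
        scen = deterministic_node_scenario(interarrival_mean=500.0,
                                           stage_mean=4.0)
        res = simulate(scen, None, horizon=1.0, warmup=0, seed=1)
        assert res.patients
        for p in res.patients:
            assert p.door_to_physician == pytest.approx(4.0 * 4)
            assert p.registration_to_physician == pytest.approx(4.0 * 3)

    def test_patient_conservation(self, case):
        res = simulate(case, None, horizon=3, warmup=0, seed=5)
        assert res.arrivals == res.departures + res.in_system_at_end

    def test_stage_timestamps_monotone_in_flow_order(self, case):
        res = simulate(case, TransferPolicy(case), horizon=3, warmup=0,
                       seed=5)
        for p in res.patients[:2000]:
            last = p.arrival_epoch
            for st in STAGES:
                if st not in p.stage_start:
                    continue
                assert p.stage_start[st] >= last - 1e-9
                if st not in p.stage_end:
                    break   # still in service at horizon end
                assert p.stage_end[st] >= p.stage_start[st]
                last = p.stage_end[st]

    def test_disabled_node_accepts_no_arrivals(self, case):
        res = simulate(case, None, horizon=2, warmup=0, seed=2)
        assert "POC4" not in res.wait_mean
        assert all(p.node_of_arrival != "POC4" for p in res.patients)

    def test_no_transfers_without_policy(self, case):
        res = simulate(case, None, horizon=3, warmup=0, seed=9)
        assert res.transfer_counts == {}
        assert all(p.transferred_to is None for p in res.patients)

    def test_transfer_rules_respected_in_simulation(self, case):
        res = simulate(case, TransferPolicy(case), horizon=5, warmup=1,
                       seed=11)
        assert sum(res.transfer_counts.values()) > 0
        for (origin, dest, insurer) in res.transfer_counts:
            assert insurer in case.node(dest).insurers
            assert insurer in case.node(origin).insurers
        for p in res.patients:
            if p.transferred_to is not None:
                assert p.triage_level in (4, 5)

    def test_occupancy_and_blocking_are_fractions(self, case):
        res = simulate(case, None, horizon=4, warmup=1, seed=3)
        for nid in res.bed_occupancy:
            assert 0.0 <= res.bed_occupancy[nid] <= 1.0
            assert 0.0 <= res.blocking_probability[nid] <= 1.0


class TestDeterminism:
    def test_identical_seeds_give_identical_patient_logs(self, case):
        a = simulate(case, TransferPolicy(case), horizon=2, warmup=0, seed=7)
        b = simulate(case, TransferPolicy(case), horizon=2, warmup=0, seed=7)
        assert [_patient_key(p) for p in a.patients] == \
            [_patient_key(p) for p in b.patients]
        assert a.transfer_counts == b.transfer_counts

    def test_different_seeds_differ(self, case):
        a = simulate(case, None, horizon=2, warmup=0, seed=1)
        b = simulate(case, None, horizon=2, warmup=0, seed=2)
        assert [_patient_key(p) for p in a.patients] != \
            [_patient_key(p) for p in b.patients]

    def test_run_replications_deterministic(self):
        scen = single_node_scenario()
        a = run_replications(scen, None, 4, 10, 1, base_seed=13)
        b = run_replications(scen, None, 4, 10, 1, base_seed=13)
        assert a == b


class TestReplicationStatistics:
    def test_half_width_shrinks_with_more_replications(self):
        scen = single_node_scenario(interarrival_mean=10.0, service_mean=6.0)
        small = run_replications(scen, None, 5, 12, 2, base_seed=31)
        large = run_replications(scen, None, 20, 12, 2, base_seed=31)
        assert large.half_width < small.half_width

    def test_required_replications_hand_value(self):
        # ceil((1.96 * 10 / 0.5)^2) = 1537
        assert required_replications(10.0, 0.5, 0.95) == 1537

    def test_required_replications_floor_is_two(self):
        assert required_replications(10.0, 1e6, 0.95) == 2

    def test_required_replications_bad_args(self):
        for args in [(0.0, 1.0, 0.95), (1.0, 0.0, 0.95), (1.0, 1.0, 1.5)]:
            with pytest.raises(ValueError):
                required_replications(*args)


class TestWarmupDetection:
    def test_constant_series_is_immediately_stable(self):
        assert detect_warmup([0.05] * 40, tolerance=1e-6) == 0

    def test_transient_then_steady(self):
        series = list(np.linspace(0.5, 0.1, 100)) + [0.1] * 100
        idx = detect_warmup(series, tolerance=1e-4)
        assert 1 <= idx <= 100

    def test_oscillation_never_stabilises(self):
        series = [0.1, 0.5] * 50
        assert detect_warmup(series, tolerance=0.01) == 100

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_warmup([], tolerance=0.1)


class TestValidationStatistics:
    def test_equal_means_give_p_one(self):
        rep = validate_against_observed([58.9] * 10, 58.9)
        assert rep.p_value == 1.0 and rep.degenerate

    def test_constant_but_wrong_mean_flags_p_zero(self):
        rep = validate_against_observed([60.0] * 10, 58.9)
        assert rep.p_value == 0.0 and rep.degenerate

    def test_large_shift_rejected(self, rng):
        x = rng.normal(58.9 + 10.0, 1.0, 30)
        rep = validate_against_observed(x, 58.9)
        assert rep.p_value < 1e-3

    def test_null_data_accepted_with_ci_covering_mean(self, rng):
        x = rng.normal(58.9, 2.0, 30)
        rep = validate_against_observed(x, 58.9)
        assert rep.p_value > 0.01
        assert rep.ci_low <= float(np.mean(x)) <= rep.ci_high


class TestScenarioComparison:
    def test_identical_samples_ci_contains_zero(self, rng):
        x = rng.exponential(30.0, 200)
        rep = compare_scenarios(x, x)
        assert rep.ci_low <= 0.0 <= rep.ci_high

    def test_constructed_shift_recovered(self, rng):
        current = rng.normal(60.0, 5.0, 400)
        proposed = current - 8.0
        rep = compare_scenarios(current, proposed)
        assert rep.p_value < 1e-6
        assert -9.0 < rep.ci_low <= -8.0 <= rep.ci_high < -7.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_scenarios([], [1.0])
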