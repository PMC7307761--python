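"""Scenario model: fixture values, validation, serialisation, generation."""

import io

import pytest

from ecnsim.distributions import DistributionSpec
from ecnsim.scenario import (
    SLOTS,
    ScenarioReferenceError,
    ScenarioValidationError,
    TransferTimeMatrix,
    case_study_scenario,
    generate_scenario,
    load_scenario,
    serialize,
)


class TestCaseFixture:
    def test_network_composition(self, case):
        assert len(case.nodes) == 10
        assert sum(n.node_class == "hospital" for n in case.nodes) == 2
        assert sum(n.node_class == "poc" for n in case.nodes) == 8

    @pytest.mark.parametrize("origin,dest,minutes", [
        ("H1", "POC1", 6), ("H1", "H2", 11), ("H2", "H1", 12),
        ("POC1", "H2", 19), ("POC6", "POC2", 35), ("POC8", "POC7", 21),
    ])
    def test_afternoon_transfer_times(self, case, origin, dest, minutes):
        assert case.transfer_times["P2"].time(origin, dest) == minutes

    def test_transfer_matrix_is_asymmetric(self, case):
        m = case.transfer_times["P2"]
        assert m.time("H1", "H2") != m.time("H2", "H1")

    @pytest.mark.parametrize("insurer,M", [
        ("S", 10.34), ("BU", 4.91), ("MS", 4.91),
        ("COM", 4.91), ("COO", 5.11), ("SV", 9.97),
    ])
    def test_unit_utilities(self, case, insurer, M):
        assert case.insurer(insurer).unit_utility_M == M

    def test_payment_parameters(self, case):
        p = case.payment
        assert (p.gamma, p.theta) == (0.19, 0.46)
        assert p.floors == {"A": 3.92, "B": 3.50, "C": 4.50}
        assert p.arrangement_rule["H2"] == "A"
        assert p.arrangement_rule["H1"] == "C"
        assert all(p.arrangement_rule[n.id] == "B"
                   for n in case.nodes if n.node_class == "poc")

    def test_population_totals(self, case):
        assert sum(r.affiliated for r in case.insurer_table) == 1_229_996
        assert case.total_population_with_access() == 1_315_283

    def test_disabled_node_has_no_ed(self, case):
        poc4 = case.node("POC4")
        assert poc4.beds is None and not poc4.ed_enabled
        assert "POC4" not in [n.id for n in case.ed_nodes()]

    def test_enabled_nodes_have_21_pipelines(self, case):
        for n in case.ed_nodes():
            assert len(n.pipelines) == 21


class TestValidation:
    def test_roundtrip_is_exact(self, case):
        assert load_scenario(serialize(case)).to_dict() == case.to_dict()

    def test_negative_transfer_time_rejected(self, case):
        doc = case.to_dict()
        doc["transfer_times"]["P1"]["minutes"]["H1"]["H2"] = -3
        with pytest.raises(ScenarioValidationError) as exc:
            load_scenario(doc)
        assert any("H1->H2" in f for f in exc.value.fields)

    def test_unknown_node_in_matrix_is_reference_error(self, case):
        doc = case.to_dict()
        doc["transfer_times"]["P1"]["minutes"]["GHOST"] = {"H1": 5.0}
        with pytest.raises(ScenarioReferenceError):
            load_scenario(doc)

    def test_bad_gamma_theta_rejected(self, case):
        doc = case.to_dict()
        doc["payment"]["gamma"] = 0.7
        doc["payment"]["theta"] = 0.7
        with pytest.raises(ScenarioValidationError):
            load_scenario(doc)

    def test_missing_pipeline_cell_rejected(self, case):
        doc = case.to_dict()
        doc["nodes"][0]["pipelines"] = doc["nodes"][0]["pipelines"][:-1]
        with pytest.raises(ScenarioValidationError):
            load_scenario(doc)

    def test_matrix_from_csv(self):
        csv = "id,A,B\nA,,7\nB,9,\n"
        m = TransferTimeMatrix.from_csv(io.StringIO(csv), "P1")
        assert m.time("A", "B") == 7 and m.time("B", "A") == 9


class TestGenerator:
    def test_seeded_determinism(self):
        a = generate_scenario(1, 2, 8, 1.0)
        b = generate_scenario(1, 2, 8, 1.0)
        assert a.to_dict() == b.to_dict()

    def test_generated_nodes_have_21_pipelines(self):
        scen = generate_scenario(3, 1, 2)
        for n in scen.ed_nodes():
            assert len(n.pipelines) == 21

    def test_demand_scale_halves_interarrival_means(self):
        base = generate_scenario(7, 1, 1, 1.0)
        doubled = generate_scenario(7, 1, 1, 2.0)
        for n1, n2 in zip(base.nodes, doubled.nodes):
            for p1, p2 in zip(n1.pipelines, n2.pipelines):
                assert p2.interarrival.mean == pytest.approx(
                    p1.interarrival.mean / 2.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_any_seed_yields_valid_scenario(self, seed):
        scen = generate_scenario(seed, 2, 3)
        scen.validate()  # would raise on any invariant violation

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_scenario(1, 0, 5)
        with pytest.raises(ValueError):
            generate_scenario(1, 1, 1, demand_scale=0.0)


class TestDistributionSpec:
    @pytest.mark.parametrize("family", ["gamma", "lognormal", "triangular",
                                        "uniform", "exponential"])
    def test_moment_matching(self, family, rng):
        mean, var = 12.0, 16.0
        spec = DistributionSpec(family, mean,
                                var if family != "exponential" else 0.0)
        x = spec.sample(rng, 200_000)
        assert x.mean() == pytest.approx(mean, rel=0.02)
        expected_var = mean**2 if family == "exponential" else var
        assert x.var() == pytest.approx(expected_var, rel=0.05)
        assert (x >= 0).all()

    def test_negative_support_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("uniform", 1.0, 100.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("weibull", 1.0, 1.0)
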