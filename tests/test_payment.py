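"""Collateral payment settlement: shares, coalition ledgers, profits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecnsim.payment import (
    DegenerateSeriesWarning,
    SettlementError,
    SettlementRule,
    destination_share,
    estimate_r,
    network_profits,
    round_half_away,
    settle_admission,
    settle_coalition,
)

FLOORS = {"A": 3.92, "B": 3.50, "C": 4.50}


def make_rule(gamma=0.19, theta=0.46, M=None, arrangement=None,
              denominator="sum"):
    return SettlementRule(
        gamma=gamma, theta=theta, floors=dict(FLOORS),
        arrangement_rule=arrangement or {"H1": "C", "H2": "A"},
        M=M or {"S": 10.34, "BU": 4.91, "MS": 4.91, "COM": 4.91,
                "COO": 5.11, "SV": 9.97},
        denominator=denominator)


class TestDestinationShare:
    @pytest.mark.parametrize("M,r,arr,expected", [
        (10.34, 0.015, "A", 6.36),   # S-insured transfer into the big hospital
        (4.91, 0.054, "A", 3.92),    # formula 3.14 < floor: floor binds
        (10.34, 0.13, "C", 7.08),
        (9.97, 0.035, "C", 6.25),
        (9.97, 0.021, "A", 6.17),    # SV under A: formula, not the misprint
    ])
    def test_worked_per_admission_shares(self, M, r, arr, expected):
        rule = make_rule()
        assert round(destination_share(M, r, arr, rule), 2) == expected

    def test_identity_limit(self):
        rule = SettlementRule(0.0, 0.0, {"A": 1e-9}, {"X": "A"},
                              {"S": 7.77})
        assert destination_share(7.77, 0.0, "A", rule) == pytest.approx(7.77)

    def test_denominator_is_one_plus_gamma_plus_theta(self):
        rule = make_rule()
        assert rule.denom == pytest.approx(1.65)
        product = make_rule(denominator="product")
        assert product.denom == pytest.approx(1.0 + 0.19 * 0.46)

    def test_unknown_arrangement_rejected(self):
        with pytest.raises(ValueError):
            destination_share(5.0, 0.1, "Z", make_rule())


class TestSettleAdmission:
    def test_same_node_keeps_full_utility(self):
        split = settle_admission("S", "H1", "H1", 0.5, make_rule())
        assert split.destination_share == 10.34
        assert split.origin_share == 0.0

    def test_shares_sum_to_M(self):
        split = settle_admission("SV", "H2", "H1", 0.035, make_rule())
        assert split.origin_share + split.destination_share == \
            pytest.approx(split.M)
        assert round(split.destination_share, 2) == 6.25

    def test_unknown_insurer_is_settlement_error(self):
        with pytest.raises(SettlementError):
            settle_admission("NOPE", "H1", "H2", 0.1, make_rule())


# printed coalition ledger for the H1->H2 direction: insurer ->
# (admissions, correlation, destination total, origin total); the COO origin
# cell is a suspected misprint in the source and is checked by conservation
# instead of the printed figure.
H1_H2_LEDGER = {
    "S": (1190, 0.015, 7569, 4735),
    "BU": (788, 0.054, 3089, 780),
    "MS": (1833, 0.043, 7185, 1814),
    "COM": (529, 0.046, 2073, 523),
    "COO": (1249, 0.016, 4896, None),
    "SV": (463, 0.021, 2856, 1759),
}


class TestCoalitionStatement:
    @pytest.fixture()
    def statement(self):
        nap = {k: v[0] for k, v in H1_H2_LEDGER.items()}
        r = {k: v[1] for k, v in H1_H2_LEDGER.items()}
        return settle_coalition("H1", "H2", nap, r, make_rule())

    def test_destination_totals_match_ledger(self, statement):
        rows = {r["insurer"]: r for r in statement.rounded_rows()}
        for insurer, (_, _, dest, _) in H1_H2_LEDGER.items():
            assert abs(rows[insurer]["destination_total"] - dest) <= 1
        # the three flagship cells to the exact dollar
        assert rows["S"]["destination_total"] == 7569
        assert rows["BU"]["destination_total"] == 3089
        assert rows["MS"]["destination_total"] == 7185

    def test_origin_totals_match_ledger(self, statement):
        rows = {r["insurer"]: r for r in statement.rounded_rows()}
        for insurer, (_, _, _, origin) in H1_H2_LEDGER.items():
            if origin is not None:
                assert abs(rows[insurer]["origin_total"] - origin) <= 1

    def test_row_conservation(self, statement):
        rule = make_rule()
        for row in statement.rows:
            assert row.origin_total + row.destination_total == \
                pytest.approx(row.nap * rule.M[row.insurer])

    def test_empty_ledger_is_all_zero(self):
        stmt = settle_coalition("H1", "H2", {}, {}, make_rule())
        assert stmt.origin_total == 0.0 and stmt.destination_total == 0.0


class TestEstimateR:
    def test_perfect_linear_relation(self):
        counts = np.arange(10.0)
        assert estimate_r(3.0 + 2.0 * counts, counts) == pytest.approx(1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(42)
        r = estimate_r(rng.normal(size=10_000), rng.normal(size=10_000))
        assert 0.0 <= r < 0.05

    def test_negative_correlation_clamped_to_zero(self):
        counts = np.arange(10.0)
        assert estimate_r(-counts + 20.0, counts) == 0.0

    def test_constant_series_warns_and_returns_zero(self):
        with pytest.warns(DegenerateSeriesWarning):
            assert estimate_r([5.0] * 10, np.arange(10.0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_r([1.0, 2.0, 3.0], [1.0, 2.0])


class TestNetworkProfits:
    def test_symmetric_directions_give_equal_profits(self):
        rule = make_rule(M={"S": 8.0}, arrangement={"H1": "A", "H2": "A"})
        a = settle_coalition("H1", "H2", {"S": 100}, {"S": 0.05}, rule)
        b = settle_coalition("H2", "H1", {"S": 100}, {"S": 0.05}, rule)
        profits = network_profits([a, b], {}, rule)
        assert profits["H1"] == pytest.approx(profits["H2"])

    def test_no_transfers_reduces_to_same_node_receipts(self):
        rule = make_rule()
        profits = network_profits([], {"H1": {"S": 10, "BU": 2}}, rule)
        assert profits["H1"] == pytest.approx(10 * 10.34 + 2 * 4.91)

    def test_duplicate_direction_rejected(self):
        rule = make_rule()
        a = settle_coalition("H1", "H2", {"S": 1}, {"S": 0.0}, rule)
        b = settle_coalition("H1", "H2", {"S": 2}, {"S": 0.0}, rule)
        with pytest.raises(ValueError):
            network_profits([a, b], {}, rule)


class TestSettlementProperties:
    @settings(max_examples=300, deadline=None)
    @given(M=st.floats(0.5, 50.0), r=st.floats(0.0, 1.0),
           gamma=st.floats(0.0, 0.5), theta=st.floats(0.0, 0.5),
           arr=st.sampled_from(["A", "B", "C"]))
    def test_conservation_and_floor_dominance(self, M, r, gamma, theta, arr):
        rule = SettlementRule(gamma, theta, dict(FLOORS), {"D": arr},
                              {"S": M})
        split = settle_admission("S", "O", "D", r, rule)
        assert split.origin_share + split.destination_share == pytest.approx(M)
        assert split.destination_share >= FLOORS[arr]
        formula = M * (1 + r) / (1 + gamma + theta)
        if formula <= FLOORS[arr]:
            assert split.destination_share == FLOORS[arr]
        else:
            assert split.destination_share == pytest.approx(formula)

    @settings(max_examples=200, deadline=None)
    @given(M=st.floats(0.5, 50.0), r=st.floats(0.0, 0.99),
           gamma=st.floats(0.0, 0.5), theta=st.floats(0.0, 0.5))
    def test_monotonicity(self, M, r, gamma, theta):
        rule = SettlementRule(gamma, theta, dict(FLOORS), {"D": "B"}, {})
        base = destination_share(M, r, "B", rule)
        assert destination_share(M, r + 0.01, "B", rule) >= base
        assert destination_share(M + 1.0, r, "B", rule) >= base
        tighter = SettlementRule(min(0.5, gamma + 0.05), theta,
                                 dict(FLOORS), {"D": "B"}, {})
        assert destination_share(M, r, "B", tighter) <= base


def test_round_half_away():
    assert round_half_away(2.5) == 3.0
    assert round_half_away(-2.5) == -3.0
    assert round_half_away(1.25, 1) == 1.3
    assert round_half_away(2.4) == 2.0
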