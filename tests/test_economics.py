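"""Discounting, per-cycle valuation, accumulation and the ICER frontier."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mhspc_cea import (
    AdverseEvent,
    AdverseEventProfile,
    CEOutcome,
    CohortTrace,
    InvalidInputError,
    ModelConfig,
    StrategyEconomics,
    accumulate,
    cycle_cost,
    cycle_qaly,
    discount_factor,
    incremental_analysis,
    net_monetary_benefit,
)


def _econ(**kw) -> StrategyEconomics:
    base = dict(
        name="X",
        drug_cost_pf_monthly=0.0,
        drug_duration_cycles=None,
        adt_cost_monthly=0.0,
        admin_cost_per_cycle=0.0,
        ae_profile=AdverseEventProfile(),
        utility_on_treatment=1.0,
        utility_pf_post_treatment=1.0,
        utility_progression=1.0,
        crpc_cost_monthly=0.0,
        death_cost_terminal=0.0,
    )
    base.update(kw)
    return StrategyEconomics(**base)


def _trace(occ, new_prog=None, new_death=None) -> CohortTrace:
    occ = np.asarray(occ, dtype=float)
    H = occ.shape[0] - 1
    return CohortTrace(
        occ,
        np.zeros(H) if new_prog is None else np.asarray(new_prog, float),
        np.zeros(H) if new_death is None else np.asarray(new_death, float),
    )


def _immortal_pf_trace(H: int) -> CohortTrace:
    return _trace(np.tile([1.0, 0.0, 0.0], (H + 1, 1)))


class TestDiscounting:
    def test_cycle_zero_is_unity(self):
        assert discount_factor(0.07, 0) == 1.0

    def test_one_year_at_three_percent(self):
        assert discount_factor(0.03, 12, 1.0) == pytest.approx(1 / 1.03)

    def test_zero_rate_is_identity(self):
        for cycle in (0, 7, 480):
            assert discount_factor(0.0, cycle) == 1.0


class TestCycleCost:
    def test_dead_cohort_costs_nothing(self):
        trace = _trace([[0, 0, 1], [0, 0, 1]])
        assert cycle_cost(_econ(drug_cost_pf_monthly=100.0), trace, 0) == 0.0

    def test_on_treatment_hand_sum(self):
        trace = _immortal_pf_trace(2)
        econ = _econ(drug_cost_pf_monthly=1440.0, adt_cost_monthly=100.0)
        assert cycle_cost(econ, trace, 0) == pytest.approx(1540.0)

    def test_terminal_death_cost_is_proportional(self):
        trace = _trace(
            [[1, 0, 0], [0.9, 0, 0.1]], new_death=[0.1]
        )
        econ = _econ(death_cost_terminal=20000.0)
        assert cycle_cost(econ, trace, 0) == pytest.approx(2000.0)

    def test_drug_stops_after_fixed_duration(self):
        trace = _immortal_pf_trace(10)
        econ = _econ(
            drug_cost_pf_monthly=500.0, drug_duration_cycles=6,
            admin_cost_per_cycle=300.0, adt_cost_monthly=100.0,
        )
        assert cycle_cost(econ, trace, 5) == pytest.approx(900.0)
        assert cycle_cost(econ, trace, 6) == pytest.approx(100.0)

    def test_ae_cost_spread_over_fixed_duration(self):
        trace = _immortal_pf_trace(10)
        profile = AdverseEventProfile((AdverseEvent("fn", 0.1, 6000.0, 0.0),))
        econ = _econ(drug_duration_cycles=6, ae_profile=profile)
        assert cycle_cost(econ, trace, 0) == pytest.approx(100.0)  # 600/6
        assert cycle_cost(econ, trace, 6) == 0.0

    def test_ae_cost_once_at_start_until_progression(self):
        trace = _immortal_pf_trace(10)
        profile = AdverseEventProfile((AdverseEvent("ht", 0.1, 6000.0, 0.0),))
        econ = _econ(ae_profile=profile)
        assert cycle_cost(econ, trace, 0) == pytest.approx(600.0)
        assert cycle_cost(econ, trace, 1) == 0.0

    def test_out_of_range_cycle_rejected(self):
        trace = _immortal_pf_trace(2)
        with pytest.raises(InvalidInputError):
            cycle_cost(_econ(), trace, 5)


class TestCycleQaly:
    def test_dead_cohort_accrues_nothing(self):
        trace = _trace([[0, 0, 1], [0, 0, 1]])
        assert cycle_qaly(_econ(), trace, 0) == 0.0

    def test_definition_one_month(self):
        trace = _immortal_pf_trace(2)
        econ = _econ(utility_on_treatment=0.8)
        assert cycle_qaly(econ, trace, 0, 1.0) == pytest.approx(0.8 / 12)

    def test_docetaxel_window_reverts_to_post_treatment_utility(self):
        trace = _immortal_pf_trace(10)
        econ = _econ(
            drug_duration_cycles=6,
            utility_on_treatment=0.77,
            utility_pf_post_treatment=0.83,
        )
        assert cycle_qaly(econ, trace, 5, 1.0) == pytest.approx(0.77 / 12)
        assert cycle_qaly(econ, trace, 7, 1.0) == pytest.approx(0.83 / 12)


class TestAccumulate:
    def test_zero_costs_but_positive_lifeyears(self, flat_life_table):
        trace = _immortal_pf_trace(480)
        econ = _econ(utility_on_treatment=0.0, utility_pf_post_treatment=0.0)
        out = accumulate(econ, trace, ModelConfig(discount_annual=0.0))
        assert out.total_cost == 0.0
        assert out.total_qalys == 0.0
        assert out.total_lys > 0.0

    def test_one_undiscounted_year(self):
        trace = _immortal_pf_trace(12)
        out = accumulate(
            _econ(), trace, ModelConfig(horizon_cycles=12, discount_annual=0.0)
        )
        assert out.total_qalys == pytest.approx(1.0)
        assert out.total_lys == pytest.approx(1.0)

    def test_discounted_totals_match_geometric_partial_sum(self):
        H = 480
        trace = _immortal_pf_trace(H)
        r = 0.03
        out = accumulate(
            _econ(), trace, ModelConfig(horizon_cycles=H, discount_annual=r)
        )
        m = (1 + r) ** (-1.0 / 12.0)
        expected = (1 - m**H) / (1 - m) / 12.0
        assert out.total_qalys == pytest.approx(expected, rel=1e-12)

    def test_matches_per_cycle_summation(self, fitted_results):
        """Vectorised totals equal the cycle-by-cycle definitional sum."""
        name = "DCX+ADT"
        trace = fitted_results.traces[name]
        econ = fitted_results.model.strategies[name]
        config = fitted_results.model.config
        cost = sum(
            discount_factor(config.discount_annual, t, config.cycle_months)
            * cycle_cost(econ, trace, t)
            for t in range(config.horizon_cycles)
        )
        qaly = sum(
            discount_factor(config.discount_annual, t, config.cycle_months)
            * cycle_qaly(econ, trace, t, config.cycle_months)
            for t in range(config.horizon_cycles)
        )
        out = accumulate(econ, trace, config)
        assert out.total_cost == pytest.approx(cost, rel=1e-12)
        assert out.total_qalys == pytest.approx(qaly, rel=1e-12)

    def test_linearity_in_costs_and_utilities(self):
        H = 60
        occ = np.zeros((H + 1, 3))
        occ[:, 0] = np.linspace(1, 0.4, H + 1)
        occ[:, 1] = 0.5 * (1 - occ[:, 0])
        occ[:, 2] = 1 - occ[:, 0] - occ[:, 1]
        trace = _trace(occ, new_death=np.full(H, 0.001))
        config = ModelConfig(horizon_cycles=H)
        econ1 = _econ(
            drug_cost_pf_monthly=100.0, crpc_cost_monthly=50.0,
            death_cost_terminal=1000.0, utility_on_treatment=0.4,
            utility_pf_post_treatment=0.4, utility_progression=0.2,
        )
        econ2 = _econ(
            drug_cost_pf_monthly=200.0, crpc_cost_monthly=100.0,
            death_cost_terminal=2000.0, utility_on_treatment=0.8,
            utility_pf_post_treatment=0.8, utility_progression=0.4,
        )
        o1 = accumulate(econ1, trace, config)
        o2 = accumulate(econ2, trace, config)
        assert o2.total_cost == pytest.approx(2 * o1.total_cost, rel=1e-12)
        assert o2.total_qalys == pytest.approx(2 * o1.total_qalys, rel=1e-12)

    def test_discounting_reduces_totals(self):
        trace = _immortal_pf_trace(120)
        undisc = accumulate(
            _econ(adt_cost_monthly=10.0), trace,
            ModelConfig(horizon_cycles=120, discount_annual=0.0),
        )
        disc = accumulate(
            _econ(adt_cost_monthly=10.0), trace,
            ModelConfig(horizon_cycles=120, discount_annual=0.03),
        )
        assert disc.total_cost < undisc.total_cost
        assert disc.total_qalys < undisc.total_qalys


# ---------------------------------------------------------------------------
# incremental analysis & dominance
# ---------------------------------------------------------------------------

def _brute_force_frontier(outcomes):
    """Independent oracle: strong dominance by pairwise enumeration; extended
    dominance by testing each strategy against every convex blend of two
    others."""
    strong = set()
    for a in outcomes:
        for b in outcomes:
            if a is b:
                continue
            if (
                b.total_cost <= a.total_cost
                and b.total_qalys >= a.total_qalys
                and (b.total_cost < a.total_cost or b.total_qalys > a.total_qalys)
            ):
                strong.add(a.strategy)
                break
    rest = [o for o in outcomes if o.strategy not in strong]
    extended = set()
    for x in rest:
        for i in rest:
            for j in rest:
                if i is j or x is i or x is j:
                    continue
                dc = j.total_cost - i.total_cost
                if dc == 0:
                    continue
                lam = (x.total_cost - i.total_cost) / dc
                if not 0.0 <= lam <= 1.0:
                    continue
                q_blend = i.total_qalys + lam * (j.total_qalys - i.total_qalys)
                if q_blend > x.total_qalys + 1e-12:
                    extended.add(x.strategy)
    return strong, {o.strategy for o in rest if o.strategy not in extended}


class TestIncrementalAnalysis:
    def test_two_strategy_incrementals(self):
        ce = incremental_analysis([
            CEOutcome("ADT", 69554.0, 3.42, 4.34),
            CEOutcome("DCX", 73144.0, 3.70, 4.69),
        ])
        row = ce.rows[1]
        assert row.incremental_cost == pytest.approx(3590.0)
        assert row.incremental_qalys == pytest.approx(0.28)
        assert row.status == "on-frontier"

    def test_strong_dominance_definition(self):
        ce = incremental_analysis([
            CEOutcome("A", 100.0, 1.0, 1.2),
            CEOutcome("B", 300.0, 1.5, 1.7),
            CEOutcome("C", 250.0, 2.0, 2.2),
        ])
        statuses = {r.strategy: r.status for r in ce.rows}
        assert statuses["B"] == "strongly-dominated"
        assert statuses["C"] == "on-frontier"
        assert [r.icer for r in ce.rows if r.strategy == "B"] == [None]

    def test_duplicate_names_rejected(self):
        with pytest.raises(InvalidInputError):
            incremental_analysis([
                CEOutcome("A", 1.0, 1.0, 1.0), CEOutcome("A", 2.0, 2.0, 2.0)
            ])

    def test_identical_pair_kept_and_flagged(self):
        ce = incremental_analysis([
            CEOutcome("A", 100.0, 1.0, 1.0),
            CEOutcome("B", 100.0, 1.0, 1.0),
        ])
        assert {r.strategy for r in ce.rows} == {"A", "B"}
        assert all(r.status != "strongly-dominated" for r in ce.rows)
        assert "tied" in ce.rows[1].note

    def test_frontier_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = rng.integers(2, 7)
            outs = [
                CEOutcome(
                    f"S{i}",
                    float(rng.uniform(1e4, 5e5)),
                    float(rng.uniform(1.0, 8.0)),
                    float(rng.uniform(8.0, 10.0)),
                )
                for i in range(n)
            ]
            ce = incremental_analysis(outs)
            strong_bf, frontier_bf = _brute_force_frontier(outs)
            strong_impl = {
                r.strategy for r in ce.rows if r.status == "strongly-dominated"
            }
            assert strong_impl == strong_bf
            assert set(ce.frontier) == frontier_bf

    def test_frontier_icers_strictly_increase_and_are_stable(self):
        rng = np.random.default_rng(3)
        outs = [
            CEOutcome(f"S{i}", float(rng.uniform(1e4, 5e5)),
                      float(rng.uniform(1.0, 8.0)), 9.0)
            for i in range(8)
        ]
        ce = incremental_analysis(outs)
        icers = [r.icer for r in ce.rows if r.status == "on-frontier"]
        assert all(a < b for a, b in zip(icers, icers[1:]))
        # re-running on the frontier subset reproduces identical ICERs
        sub = [o for o in outs if o.strategy in ce.frontier]
        ce2 = incremental_analysis(sub)
        icers2 = [r.icer for r in ce2.rows if r.status == "on-frontier"]
        assert icers2 == pytest.approx(icers)


class TestNetMonetaryBenefit:
    def test_zero_wtp_is_negative_cost(self):
        o = CEOutcome("A", 1234.0, 5.0, 6.0)
        assert net_monetary_benefit(o, 0.0) == -1234.0

    def test_arithmetic(self):
        o = CEOutcome("AA", 139254.0, 5.40, 6.48)
        assert net_monetary_benefit(o, 100_000.0) == pytest.approx(400_746.0)

    @given(
        c1=st.floats(1e3, 1e6), c2=st.floats(1e3, 1e6),
        q1=st.floats(0.5, 10.0), dq=st.floats(0.01, 5.0),
        wtp=st.floats(0.0, 5e5),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_nmb_icer_ranking_consistency(self, c1, c2, q1, dq, wtp):
        """The more effective strategy has higher NMB iff its pairwise ICER
        is below the WTP."""
        lo = CEOutcome("lo", min(c1, c2), q1, q1)
        hi = CEOutcome("hi", max(c1, c2) + 1.0, q1 + dq, q1 + dq)
        icer = (hi.total_cost - lo.total_cost) / dq
        nmb_hi = net_monetary_benefit(hi, wtp)
        nmb_lo = net_monetary_benefit(lo, wtp)
        if icer < wtp:
            assert nmb_hi > nmb_lo
        elif icer > wtp:
            assert nmb_hi < nmb_lo
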