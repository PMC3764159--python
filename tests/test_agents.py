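import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from smallholder.agents import (
    BehaviorParams,
    ExpectationState,
    SettlementAgent,
    allocate_labor,
    certainty_equivalent,
    expect,
    market_utility,
    shadow_price,
    subsistence_utility,
    update_stocks,
)
from smallholder.config_io import make_fixture
from smallholder.landscape import (
    CellState,
    GridState,
    LandUse,
    LandUseParams,
    LandscapeConfig,
    generate_topography,
)
from smallholder.market import CostPriceParams, MarketState, local_market

NEUTRAL = LandscapeConfig(rows=10, cols=10, roughness=0.0,
                          slope_constraint_on=False, precip_constraint_on=False)


class TestExpect:
    @pytest.mark.parametrize(
        "history,forecast",
        [((100, 100), 100), ((100, 110), 120), ((50, 10), 0), ((80,), 80)],
    )
    def test_trend_extrapolation(self, history, forecast):
        assert expect(history) == forecast

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            expect([])


class TestCertaintyEquivalent:
    def test_risk_neutral_and_riskless_limits(self):
        assert certainty_equivalent(100.0, 20.0, 0.0) == 100.0
        assert certainty_equivalent(100.0, 0.0, 0.9) == 100.0

    def test_risk_discount(self):
        assert certainty_equivalent(100.0, 20.0, 0.5) == 90.0

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_risk_aversion(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert certainty_equivalent(100, 30, lo) >= certainty_equivalent(100, 30, hi)


def _one_cell_grid(params, land_use=LandUse.INTENSIVE_AG, yield_state=1.0):
    terrain = generate_topography(10, 10, seed=0, roughness=0.0)
    cells = [CellState() for _ in range(100)]
    cells[0] = CellState(land_use=land_use, yield_state=yield_state, owner=0,
                         prev_productive_use=LandUse.EXTENSIVE_AG)
    return GridState(terrain, NEUTRAL, params, cells)


def _agent(cells=(0,), **kwargs):
    defaults = dict(id=0, cell_indices=np.array(cells), n_households=1.0,
                    risk_pref=0.0, food_stock=0.0, money_stock=0.0)
    defaults.update(kwargs)
    return SettlementAgent(**defaults)


class TestShadowPrice:
    def test_unit_cost_of_self_provisioning(self):
        # inputs 150 $/ha + 10 pw at 10 $/pw over 2,500 kg -> 0.10 $/kg
        params = LandUseParams(base_yield={LandUse.INTENSIVE_AG: 2500.0,
                                           LandUse.EXTENSIVE_AG: 0.0,
                                           LandUse.PASTURE: 0.0})
        grid = _one_cell_grid(params)
        m = MarketState(mi=0.5, farmgate_price=0.09, food_price=0.2,
                        input_cost=150.0, wage=10.0, transaction_cost=0.0)
        assert shadow_price(_agent(), m, grid) == pytest.approx(0.10)

    def test_costless_production_has_zero_shadow_price(self):
        grid = _one_cell_grid(LandUseParams(), land_use=LandUse.EXTENSIVE_AG)
        m = MarketState(mi=0.0, farmgate_price=0.039, food_price=0.26,
                        input_cost=0.0, wage=0.0, transaction_cost=0.0)
        assert shadow_price(_agent(), m, grid) == 0.0

    def test_exhausted_land_gives_infinite_sentinel(self):
        params = LandUseParams(base_yield={LandUse.INTENSIVE_AG: 0.0,
                                           LandUse.EXTENSIVE_AG: 2700.0,
                                           LandUse.PASTURE: 0.0})
        grid = _one_cell_grid(params, land_use=LandUse.EXTENSIVE_AG, yield_state=0.0)
        m = MarketState(mi=0.5, farmgate_price=0.09, food_price=0.2,
                        input_cost=150.0, wage=10.0, transaction_cost=0.0)
        assert shadow_price(_agent(), m, grid) == math.inf


class TestUtilities:
    def test_subsistence_utility_is_yield_per_person_week(self):
        cell = CellState(land_use=LandUse.EXTENSIVE_AG)
        u = subsistence_utility(cell, LandUse.EXTENSIVE_AG, _agent(risk_pref=0.7),
                                0.0, NEUTRAL, LandUseParams(), yield_cv=0.0)
        assert u == pytest.approx(2700.0 / 6.0)

    def test_market_utility_profit_per_hectare(self):
        # 0.13 x 3500 - 150 inputs - 10 pw x 10 $/pw = 205 $/ha
        cell = CellState(land_use=LandUse.INTENSIVE_AG)
        m = MarketState(mi=0.5, farmgate_price=0.13, food_price=0.2,
                        input_cost=150.0, wage=10.0, transaction_cost=0.0)
        u = market_utility(cell, LandUse.INTENSIVE_AG, _agent(), m,
                           0.0, NEUTRAL, LandUseParams(), yield_cv=0.0)
        assert u == pytest.approx(205.0)

    def test_degraded_cell_has_lower_subsistence_utility(self):
        fresh = CellState(land_use=LandUse.EXTENSIVE_AG, yield_state=1.0)
        worn = CellState(land_use=LandUse.EXTENSIVE_AG, yield_state=0.5)
        args = (LandUse.EXTENSIVE_AG, _agent(), 0.0, NEUTRAL, LandUseParams())
        assert subsistence_utility(fresh, *args) > subsistence_utility(worn, *args)

    def test_risk_aversion_lowers_utility_under_noise(self):
        cell = CellState(land_use=LandUse.EXTENSIVE_AG)
        args = (LandUse.EXTENSIVE_AG,)
        u0 = subsistence_utility(cell, *args, _agent(risk_pref=0.0), 0.0, NEUTRAL,
                                 LandUseParams(), yield_cv=0.3)
        u1 = subsistence_utility(cell, *args, _agent(risk_pref=1.0), 0.0, NEUTRAL,
                                 LandUseParams(), yield_cv=0.3)
        assert u1 < u0


class TestUpdateStocks:
    MARKET = local_market(0.5, CostPriceParams())

    def test_initial_stock_covers_one_year(self):
        agent = _agent(food_stock=2580.0)
        agent, log = update_stocks(agent, 0, 0, 0, 0, self.MARKET)
        assert agent.food_stock == 0.0
        assert log.consumption == 2580.0
        assert log.consumption_shortfall == 0.0

    def test_harvest_equal_to_consumption_is_steady(self):
        agent = _agent(food_stock=500.0)
        agent, _ = update_stocks(agent, 2580.0, 0, 0, 0, self.MARKET)
        assert agent.food_stock == 500.0

    def test_sale_revenue(self):
        agent = _agent(food_stock=1000.0)
        m = MarketState(mi=1.0, farmgate_price=0.13, food_price=0.13,
                        input_cost=100.0, wage=290.0, transaction_cost=0.0)
        agent, log = update_stocks(agent, 1000.0, 1000.0, 0, 0, m)
        assert log.sales_revenue == pytest.approx(130.0)
        assert agent.money_stock == pytest.approx(130.0)

    def test_overselling_rejected(self):
        agent = _agent(food_stock=10.0)
        with pytest.raises(ValueError):
            update_stocks(agent, 100.0, 200.0, 0, 0, self.MARKET)

    def test_shortfall_logged_when_food_runs_out(self):
        agent = _agent(food_stock=1000.0)
        agent, log = update_stocks(agent, 0, 0, 0, 0, self.MARKET)
        assert agent.food_stock == 0.0
        assert log.consumption_shortfall == pytest.approx(1580.0)


class TestAllocateLabor:
    def test_toy_matches_precomputed_optimum(self):
        fx = make_fixture("toy_3cell")
        a = allocate_labor(fx["agent"], fx["market"], fx["grid"], fx["behavior"],
                           yield_cv=0.0)
        exp = fx["expected"]
        assert a.labor_subsistence == pytest.approx(exp["labor_subsistence"])
        assert a.nonfarm_weeks == pytest.approx(exp["nonfarm_weeks"])
        plan = a.cell_plan[exp["subsistence_cell"]]
        assert plan.category == "subsistence"
        assert plan.fraction == pytest.approx(exp["subsistence_fraction"])

    def test_toy_matches_brute_force_enumeration(self):
        """Greedy allocation equals the exhaustive satisficing optimum.

        The oracle scans cultivated fractions of the three cells on a fine
        grid, computes the implied non-farm weeks analytically, and ranks
        plans lexicographically: food target coverage, then cash target
        coverage, then least labor.
        """
        fx = make_fixture("toy_3cell")
        agent, market, grid = fx["agent"], fx["market"], fx["grid"]
        a = allocate_labor(agent, market, grid, fx["behavior"], yield_cv=0.0)

        F = fx["expected"]["food_target_kg"]
        D = fx["expected"]["cash_target"]
        w_net = fx["expected"]["net_wage"]
        yields = np.array([2700.0, 2025.0, 1350.0])
        endow = agent.labor_endowment

        step = 0.005
        fr = np.arange(0.0, 1.0 + step / 2, step)
        f0, f1, f2 = np.meshgrid(fr, fr, fr, indexing="ij")
        prod = yields[0] * f0 + yields[1] * f1 + yields[2] * f2
        labor = 6.0 * (f0 + f1 + f2)
        feasible = labor <= endow
        food_score = np.minimum(prod, F)
        nonfarm = np.minimum(D / w_net, np.maximum(endow - labor, 0.0))
        cash_score = np.minimum(nonfarm * w_net, D)
        total_labor = labor + nonfarm
        # lexicographic argmax: food coverage, cash coverage, then least labor
        mask = feasible & (food_score >= food_score[feasible].max() - 1e-6)
        mask &= cash_score >= cash_score[mask].max() - 1e-6
        mask &= total_labor <= total_labor[mask].min() + 1e-9
        best = tuple(idx[0] for idx in np.nonzero(mask))
        best_fracs = np.array([fr[best[0]], fr[best[1]], fr[best[2]]])

        got_fracs = np.zeros(3)
        for ci, plan in a.cell_plan.items():
            got_fracs[ci] = plan.fraction
        assert np.all(np.abs(got_fracs - best_fracs) <= step + 1e-9)
        assert abs(a.nonfarm_weeks - float(nonfarm[best])) <= 6 * step

    def test_nonfarm_weeks_monotone_in_market_influence(self):
        """More market access never reduces non-farm engagement on the toy."""
        weeks = []
        for mi in (0.2, 0.35, 0.5, 0.65, 0.8):
            fx = make_fixture("toy_3cell")
            m = local_market(mi, CostPriceParams())
            for _ in range(2):  # flat expectations at this market's prices
                fx["agent"].expectations.observe("farmgate_price", m.farmgate_price)
                fx["agent"].expectations.observe("food_price", m.food_price)
                fx["agent"].expectations.observe("wage", m.wage)
            a = allocate_labor(fx["agent"], m, fx["grid"], fx["behavior"],
                               yield_cv=0.0)
            weeks.append(a.nonfarm_weeks)
        assert all(b >= a - 1e-9 for a, b in zip(weeks, weeks[1:]))

    def test_no_deficit_and_no_cash_needs_is_idle(self):
        fx = make_fixture("toy_3cell")
        agent = fx["agent"]
        agent.food_stock = 10 * agent.annual_food_need
        agent.money_stock = 100 * agent.money_reserve
        a = allocate_labor(agent, fx["market"], fx["grid"], fx["behavior"])
        assert a.total_labor == 0.0

    def test_isolated_market_has_no_nonfarm_labor(self):
        fx = make_fixture("toy_3cell")
        m = local_market(0.0, CostPriceParams())
        a = allocate_labor(fx["agent"], m, fx["grid"], fx["behavior"])
        assert a.nonfarm_weeks == 0.0

    def test_labor_never_exceeds_endowment(self):
        fx = make_fixture("toy_3cell")
        agent = fx["agent"]
        agent.food_stock = 0.0
        a = allocate_labor(agent, fx["market"], fx["grid"], fx["behavior"])
        assert a.total_labor <= agent.labor_endowment + 1e-9
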