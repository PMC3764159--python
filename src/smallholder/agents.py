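"""Settlement agents: expectations, risk weighting, and annual labor allocation.

A settlement agent aggregates all smallholder households of one settlement
(one contiguous 100-ha block).  Households are identical within a settlement:
each has 4 people (3 adult-equivalent consumers), supplies at most 96
person-weeks of labor per year, and requires 860 kg grain-equivalent per
adult-equivalent per year.

Decision logic (annually, see :func:`allocate_labor`):

1. Form backward-looking expectations (linear trend extrapolation of the last
   two observations) of yields, prices, and wages; risk-weight them with the
   certainty equivalent ``CE = mean - R_pref * sd``.
2. Classify the market-participation regime from the shadow price (unit cost
   of self-provisioned food) relative to farm-gate and food prices.
3. Satisfice: allocate labor to the highest-utility subsistence cells until
   expected production covers the food target (annual need plus replenishment
   of a one-year stock reserve), then earn cash -- via market-oriented
   cropping or non-farm wages, whichever pays more per person-week -- until
   the cash target (required input/food spending plus an aspiration that
   grows with market influence) is covered.  Remaining labor stays home.
4. Year-over-year reallocation is damped: each activity's labor can move at
   most a fraction lambda of the settlement's total labor, with lambda scaled
   by the magnitude of recent stock changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .landscape import (
    CellState,
    GridState,
    LandUse,
    LandUseParams,
    LandscapeConfig,
    potential_yield,
)
from .market import MarketState, Regime, classify_regime

HOUSEHOLD_SIZE = 4
CONSUMERS_PER_HOUSEHOLD = 3.0          # 2 adults + 2 children at one-half
LABOR_PER_HOUSEHOLD = 96.0             # person-weeks yr^-1
SUBSISTENCE_PER_CAPITA = 860.0         # kg yr^-1 per adult-equivalent
INITIAL_FOOD_PER_HOUSEHOLD = 2580.0    # kg, one year's subsistence
INITIAL_MONEY_PER_HOUSEHOLD = 1426.0   # $


@dataclass(frozen=True)
class BehaviorParams:
    """Tunable behavioral constants of the allocation heuristic."""

    lambda_0: float = 0.5            # max fraction of labor reallocated per year
    lambda_min: float = 0.05         # floor keeping adjustment possible
    aspiration_exponent: float = 4.0  # cash aspiration ~ mi**exponent
    aspiration_per_household: float = INITIAL_MONEY_PER_HOUSEHOLD  # $ scale
    food_reserve_years: float = 1.0  # stock buffer target, in years of need
    sales_income_safety: float = 0.8  # discount on expected sales when budgeting cash


class ExpectationState:
    """Last two observations per tracked quantity, with trend forecasts."""

    def __init__(self, initial: dict[str, float] | None = None):
        self._hist: dict[str, list[float]] = {}
        if initial:
            for k, v in initial.items():
                self._hist[k] = [float(v)]

    def observe(self, key: str, value: float) -> None:
        h = self._hist.setdefault(key, [])
        h.append(float(value))
        del h[:-2]

    def forecast(self, key: str, default: float = 0.0) -> float:
        h = self._hist.get(key)
        if not h:
            return default
        return expect(h)


def expect(history) -> float:
    """One-period-ahead linear trend extrapolation, clamped at zero.

    With observations ``(x_{t-1}, x_t)`` the forecast is ``2 x_t - x_{t-1}``;
    a single observation forecasts itself.
    """
    h = list(history)
    if len(h) == 0:
        raise ValueError("history must contain at least one observation")
    if len(h) == 1:
        return max(0.0, float(h[0]))
    return max(0.0, float(h[-1]) + (float(h[-1]) - float(h[-2])))


def certainty_equivalent(mean: float, sd: float, r_pref: float) -> float:
    """Risk-adjusted value ``max(0, mean - R_pref * sd)``."""
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if not (0.0 <= r_pref <= 1.0):
        raise ValueError("r_pref must be in [0, 1]")
    return max(0.0, mean - r_pref * sd)


@dataclass
class SettlementAgent:
    """Aggregate of the smallholder households of one settlement."""

    id: int
    cell_indices: np.ndarray
    n_households: float
    risk_pref: float
    food_stock: float = 0.0
    money_stock: float = 0.0
    expectations: ExpectationState = field(default_factory=ExpectationState)
    prev_allocation: "ActivityAllocation | None" = None
    prev_food_stock: float | None = None
    prev_money_stock: float | None = None
    failed: bool = False

    @property
    def labor_endowment(self) -> float:
        return self.n_households * LABOR_PER_HOUSEHOLD

    @property
    def annual_food_need(self) -> float:
        return self.n_households * CONSUMERS_PER_HOUSEHOLD * SUBSISTENCE_PER_CAPITA

    @property
    def money_reserve(self) -> float:
        return self.n_households * INITIAL_MONEY_PER_HOUSEHOLD


@dataclass
class CellPlan:
    use: LandUse
    fraction: float          # cultivated area fraction of the 1-ha cell
    category: str            # "subsistence" or "market"
    labor: float             # person-weeks committed
    expected_yield: float    # CE kg ha^-1 (full cell)
    cash_cost: float         # $ for the cultivated fraction (inputs)


@dataclass
class ActivityAllocation:
    """One settlement-year labor plan."""

    cell_plan: dict[int, CellPlan] = field(default_factory=dict)
    nonfarm_weeks: float = 0.0
    planned_purchase_kg: float = 0.0
    regime: Regime = Regime.SUBSISTENCE_GAP
    shadow_price: float = math.inf
    labor_subsistence: float = 0.0
    labor_market: float = 0.0
    lambda_applied: float | None = None
    expected_production: float = 0.0
    expected_cash_income: float = 0.0
    aspiration_spending: float = 0.0
    failed: bool = False

    @property
    def labor_nonfarm(self) -> float:
        return self.nonfarm_weeks

    @property
    def total_labor(self) -> float:
        return self.labor_subsistence + self.labor_market + self.nonfarm_weeks


def wage_opportunity(market: MarketState, expected_weeks: float = LABOR_PER_HOUSEHOLD) -> float:
    """Net non-farm wage per person-week: wage less amortized transaction cost."""
    if expected_weeks <= 0:
        return 0.0
    return max(0.0, market.wage - market.transaction_cost / expected_weeks)


def subsistence_utility(
    cell: CellState,
    use: LandUse,
    agent: SettlementAgent,
    slope_pct: float,
    config: LandscapeConfig,
    params: LandUseParams,
    yield_cv: float = 0.0,
) -> float:
    """Expected kg of food per person-week of labor on ``cell`` under ``use``."""
    labor = params.labor_cost(cell.land_use, use)
    if labor <= 0:
        raise ValueError("labor cost must be positive")
    ey = potential_yield(cell, use, slope_pct, config, params)
    return certainty_equivalent(ey, ey * yield_cv, agent.risk_pref) / labor


def market_utility(
    cell: CellState,
    use: LandUse,
    agent: SettlementAgent,
    market: MarketState,
    slope_pct: float,
    config: LandscapeConfig,
    params: LandUseParams,
    yield_cv: float = 0.0,
) -> float:
    """Expected profit in $ ha^-1 of producing ``use`` on ``cell`` for the market.

    Certainty-equivalent revenue less input costs less the opportunity cost
    of labor at the net non-farm wage.
    """
    labor = params.labor_cost(cell.land_use, use)
    ey = potential_yield(cell, use, slope_pct, config, params)
    rev = market.farmgate_price * ey
    ce_rev = certainty_equivalent(rev, rev * yield_cv, agent.risk_pref)
    inputs = market.input_cost if use == LandUse.INTENSIVE_AG else 0.0
    return ce_rev - inputs - labor * wage_opportunity(market)


def shadow_price(agent: SettlementAgent, market: MarketState, grid: GridState) -> float:
    """Internal unit cost ($ kg^-1) of self-provisioning one kg of food.

    Minimum over the agent's cells and staple uses of
    ``(input cost + labor cost x net wage) / expected yield``; +inf when the
    agent has no cell with positive expected yield.
    """
    if len(agent.cell_indices) == 0:
        raise ValueError("agent owns no cells")
    w_net = wage_opportunity(market)
    best = math.inf
    for idx in agent.cell_indices:
        cell = grid.cells[idx]
        if cell.land_use == LandUse.DWELLING:
            continue
        for use in (LandUse.EXTENSIVE_AG, LandUse.INTENSIVE_AG):
            ey = grid.potential_yield_of(int(idx), use)
            if ey <= 0:
                continue
            labor = grid.params.labor_cost(cell.land_use, use)
            inputs = market.input_cost if use == LandUse.INTENSIVE_AG else 0.0
            best = min(best, (inputs + labor * w_net) / ey)
    return best


# ---------------------------------------------------------------------------
# allocation internals

_USE_OPTIONS = (LandUse.INTENSIVE_AG, LandUse.EXTENSIVE_AG, LandUse.PASTURE)


def _cell_option_table(agent, market, grid, yield_cv, exp_farmgate, yield_factor):
    """Per (cell, use) expected CE yields, labor, cash costs, and utilities.

    Returns dict of flat arrays over candidate (cell, use) pairs.
    """
    idxs, uses, ce_yield, labor, cash = [], [], [], [], []
    r = agent.risk_pref
    for idx in agent.cell_indices:
        cell = grid.cells[idx]
        if cell.land_use == LandUse.DWELLING:
            continue
        for use in _USE_OPTIONS:
            ey = grid.potential_yield_of(int(idx), use) * yield_factor
            lab = grid.params.labor_cost(cell.land_use, use)
            idxs.append(int(idx))
            uses.append(use)
            ce_yield.append(certainty_equivalent(ey, ey * yield_cv, r))
            labor.append(lab)
            cash.append(market.input_cost if use == LandUse.INTENSIVE_AG else 0.0)
    ce_yield = np.array(ce_yield) if ce_yield else np.zeros(0)
    labor = np.array(labor) if labor else np.zeros(0)
    cash = np.array(cash) if cash else np.zeros(0)
    rev = exp_farmgate * ce_yield
    earn_per_ha = rev - cash                     # $ ha^-1 net of inputs
    earn_per_pw = np.divide(
        earn_per_ha, labor, out=np.zeros_like(earn_per_ha), where=labor > 0
    )
    return {
        "idx": np.array(idxs, dtype=int) if idxs else np.zeros(0, dtype=int),
        "use": uses,
        "ce_yield": ce_yield,
        "labor": labor,
        "cash": cash,
        "earn_per_ha": earn_per_ha,
        "earn_per_pw": earn_per_pw,
    }


def _greedy_fill(order, table, target, target_per_row, labor_budget, taken_cells):
    """Take rows of ``table`` in ``order`` until ``target`` of the per-row
    quantity is accumulated or the labor budget runs out; the marginal cell is
    taken fractionally.  Returns (plans, labor_used, amount_accumulated).

    ``target_per_row[i]`` is the amount (kg or $) delivered by row ``i`` at
    fraction 1.  ``target=None`` means fill the whole labor budget.
    """
    plans: list[tuple[int, int, float]] = []  # (row, cell idx, fraction)
    labor_used = 0.0
    got = 0.0
    for row in order:
        if target is not None and got >= target - 1e-9:
            break
        if labor_budget - labor_used <= 1e-9:
            break
        ci = int(table["idx"][row])
        if ci in taken_cells:
            continue
        per = float(target_per_row[row])
        if per <= 0:
            continue
        lab = float(table["labor"][row])
        frac = 1.0
        if target is not None and got + per > target:
            frac = (target - got) / per
        frac = min(frac, (labor_budget - labor_used) / lab)
        if frac <= 1e-9:
            continue
        plans.append((int(row), ci, float(frac)))
        taken_cells.add(ci)
        labor_used += lab * frac
        got += per * frac
    return plans, labor_used, got


def allocate_labor(
    agent: SettlementAgent,
    market: MarketState,
    grid: GridState,
    behavior: BehaviorParams = BehaviorParams(),
    yield_cv: float = 0.0,
    prev_allocation: "ActivityAllocation | None" = None,
) -> ActivityAllocation:
    """Build the settlement's annual activity allocation (see module docstring)."""
    endow = agent.labor_endowment
    alloc = ActivityAllocation()
    if endow <= 0 or len(agent.cell_indices) == 0:
        return alloc

    exp_farmgate = agent.expectations.forecast("farmgate_price", market.farmgate_price)
    exp_food = agent.expectations.forecast("food_price", market.food_price)
    exp_wage = agent.expectations.forecast("wage", market.wage)
    yield_factor = agent.expectations.forecast("yield_factor", 1.0)
    w_net = max(0.0, exp_wage - market.transaction_cost / LABOR_PER_HOUSEHOLD)

    table = _cell_option_table(agent, market, grid, yield_cv, exp_farmgate, yield_factor)
    if table["ce_yield"].size == 0:
        return alloc

    # best cash-earning rate ($ per person-week) across channels; converts
    # monetary input costs into labor-equivalents for the subsistence ranking
    best_mkt_pw = float(table["earn_per_pw"].max(initial=0.0))
    earn_rate = max(w_net, best_mkt_pw)

    with np.errstate(divide="ignore", invalid="ignore"):
        labor_eq = table["labor"] + np.where(
            table["cash"] > 0,
            table["cash"] / earn_rate if earn_rate > 0 else math.inf,
            0.0,
        )
        sub_util = np.where(labor_eq > 0, table["ce_yield"] / labor_eq, 0.0)
    sub_util = np.nan_to_num(sub_util, nan=0.0, posinf=0.0)

    # --- regime from the shadow price
    sp = shadow_price(agent, market, grid)
    regime = classify_regime(sp, market)
    alloc.shadow_price = sp
    alloc.regime = regime

    # --- food target
    need = agent.annual_food_need
    reserve = behavior.food_reserve_years * need
    food_target = max(0.0, need + reserve - agent.food_stock)
    purchase_kg = 0.0
    if regime == Regime.SELL_AND_BUY and exp_food > 0:
        # market food availability ramps with integration
        purchase_kg = market.mi * food_target
    produce_target = food_target - purchase_kg

    use_order = {u: i for i, u in enumerate(_USE_OPTIONS)}
    use_rank = np.array([use_order[u] for u in table["use"]])

    # ranking: utility desc, then lowest cell index, then land-use enum order
    sub_order = np.lexsort((use_rank, table["idx"], -sub_util))
    sub_order = [r for r in sub_order if sub_util[r] > 0]

    taken: set[int] = set()
    sub_plans, sub_labor, sub_prod = _greedy_fill(
        sub_order, table, produce_target, table["ce_yield"], endow, taken
    )
    if produce_target > 0 and not sub_order and agent.food_stock <= 0 and purchase_kg <= 0:
        alloc.failed = True

    # --- cash target: required spending + MI-scaled aspiration
    required_cash = purchase_kg * exp_food + sum(
        float(table["cash"][r]) * f for r, _, f in sub_plans
    )
    aspiration = (
        agent.n_households
        * behavior.aspiration_per_household
        * market.mi ** behavior.aspiration_exponent
    )
    cash_deficit = max(
        0.0, required_cash + aspiration + agent.money_reserve - agent.money_stock
    )

    mkt_order = np.lexsort((use_rank, table["idx"], -table["earn_per_pw"]))
    mkt_order = [
        r
        for r in mkt_order
        if table["earn_per_pw"][r] > 0 and table["earn_per_pw"][r] > w_net
    ]

    mkt_plans, mkt_labor, mkt_cash = _greedy_fill(
        mkt_order, table, cash_deficit, table["earn_per_ha"], endow - sub_labor, taken
    )
    nonfarm = 0.0
    if w_net > 0 and cash_deficit - mkt_cash > 1e-9:
        nonfarm = min(
            (cash_deficit - mkt_cash) / w_net, endow - sub_labor - mkt_labor
        )

    # --- damped reallocation toward the desired plan
    lam = None
    if prev_allocation is not None and agent.prev_food_stock is not None:
        d_food = abs(agent.food_stock - agent.prev_food_stock)
        d_money = abs(agent.money_stock - (agent.prev_money_stock or 0.0))
        scale_f = d_food / need if need > 0 else 1.0
        scale_m = d_money / max(required_cash + aspiration, 1.0)
        lam = float(
            np.clip(behavior.lambda_0 * max(scale_f, scale_m),
                    behavior.lambda_min, behavior.lambda_0)
        )
        cap = lam * endow

        def clamp(desired, prev):
            return float(np.clip(desired, prev - cap, prev + cap))

        sub_budget = clamp(sub_labor, prev_allocation.labor_subsistence)
        mkt_budget = clamp(mkt_labor, prev_allocation.labor_market)
        nonfarm_b = clamp(nonfarm, prev_allocation.nonfarm_weeks)
        if sub_budget + mkt_budget + nonfarm_b > endow:
            over = sub_budget + mkt_budget + nonfarm_b - endow
            nonfarm_b = max(0.0, nonfarm_b - over)
        # refill with clamped budgets: targets may overshoot (surplus) or be cut
        taken = set()
        sub_plans, sub_labor, sub_prod = _greedy_fill(
            sub_order, table, None, table["ce_yield"], sub_budget, taken
        )
        mkt_plans, mkt_labor, mkt_cash = _greedy_fill(
            mkt_order, table, None, table["earn_per_ha"], mkt_budget, taken
        )
        nonfarm = nonfarm_b if w_net > 0 else 0.0
    alloc.lambda_applied = lam

    # --- affordability: inputs must be payable from stock + budgeted income
    def planned_inputs():
        return sum(
            float(table["cash"][r]) * f for r, _, f in sub_plans + mkt_plans
        )

    expected_income = (
        mkt_cash * behavior.sales_income_safety + nonfarm * w_net
    )
    budget = agent.money_stock + expected_income
    while planned_inputs() + purchase_kg * exp_food > budget + 1e-9:
        # drop the least attractive input-using plan
        droppable = [
            (i, lst) for lst in (sub_plans, mkt_plans) for i, (r, _, _) in enumerate(lst)
            if table["cash"][lst[i][0]] > 0
        ]
        if not droppable:
            purchase_kg = max(0.0, (budget - planned_inputs()) / exp_food) if exp_food > 0 else 0.0
            break
        i, lst = droppable[-1]
        r, ci, f = lst.pop(i)
        if lst is sub_plans:
            sub_labor -= table["labor"][r] * f
            sub_prod -= table["ce_yield"][r] * f
        else:
            mkt_labor -= table["labor"][r] * f
            mkt_cash -= table["earn_per_ha"][r] * f
        expected_income = mkt_cash * behavior.sales_income_safety + nonfarm * w_net
        budget = agent.money_stock + expected_income

    for r, ci, f in sub_plans:
        alloc.cell_plan[ci] = CellPlan(
            use=table["use"][r], fraction=f, category="subsistence",
            labor=float(table["labor"][r]) * f,
            expected_yield=float(table["ce_yield"][r]),
            cash_cost=float(table["cash"][r]) * f,
        )
    for r, ci, f in mkt_plans:
        alloc.cell_plan[ci] = CellPlan(
            use=table["use"][r], fraction=f, category="market",
            labor=float(table["labor"][r]) * f,
            expected_yield=float(table["ce_yield"][r]),
            cash_cost=float(table["cash"][r]) * f,
        )
    alloc.nonfarm_weeks = float(nonfarm)
    alloc.planned_purchase_kg = float(purchase_kg)
    alloc.labor_subsistence = float(sub_labor)
    alloc.labor_market = float(mkt_labor)
    alloc.expected_production = float(sub_prod)
    alloc.expected_cash_income = float(mkt_cash + nonfarm * w_net)
    alloc.aspiration_spending = float(aspiration)
    return alloc


@dataclass
class StockLog:
    """Exact cash/food flows of one settlement-year (for mass-balance checks)."""

    harvest: float = 0.0
    consumption: float = 0.0
    surplus_consumption: float = 0.0
    consumption_shortfall: float = 0.0
    sales_kg: float = 0.0
    purchases_kg: float = 0.0
    sales_revenue: float = 0.0
    wage_income: float = 0.0
    purchase_cost: float = 0.0
    input_costs: float = 0.0
    transaction_costs: float = 0.0
    aspiration_spent: float = 0.0
    money_overdraft: float = 0.0


def update_stocks(
    agent: SettlementAgent,
    harvest_kg: float,
    sales_kg: float,
    purchases_kg: float,
    wage_income: float,
    market: MarketState,
    input_costs: float = 0.0,
    transaction_costs: float = 0.0,
    aspiration_spending: float = 0.0,
) -> tuple[SettlementAgent, StockLog]:
    """Apply one year's production, trade, and consumption to the stocks.

    Consumption is the settlement's annual subsistence requirement, capped by
    available food (the shortfall is logged).  When the remaining stock
    exceeds the one-year reserve, households consume part of the excess
    (richer diets, feed, festivals) up to half the annual requirement; this
    keeps the risk-planning production margin from accumulating without
    bound.  Aspiration spending is capped so it never draws the money stock
    below the settlement's reserve.  Stocks are floored at zero with any
    overdraft logged.
    """
    for name, v in (("harvest", harvest_kg), ("sales", sales_kg),
                    ("purchases", purchases_kg), ("wage income", wage_income)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if sales_kg > harvest_kg + agent.food_stock + 1e-9:
        raise ValueError("cannot sell more food than harvest plus stock")

    log = StockLog(harvest=harvest_kg, sales_kg=sales_kg, wage_income=wage_income,
                   input_costs=input_costs, transaction_costs=transaction_costs)
    agent.prev_food_stock = agent.food_stock
    agent.prev_money_stock = agent.money_stock

    money = agent.money_stock + sales_kg * market.farmgate_price + wage_income
    log.sales_revenue = sales_kg * market.farmgate_price
    money -= input_costs + transaction_costs
    affordable_kg = max(0.0, money) / market.food_price if market.food_price > 0 else 0.0
    purchases_kg = min(purchases_kg, affordable_kg)
    log.purchases_kg = purchases_kg
    log.purchase_cost = purchases_kg * market.food_price
    money -= log.purchase_cost
    spend = min(aspiration_spending, max(0.0, money - agent.money_reserve))
    log.aspiration_spent = spend
    money -= spend
    if money < 0:
        log.money_overdraft = -money
        money = 0.0
    agent.money_stock = money

    available = agent.food_stock + harvest_kg - sales_kg + purchases_kg
    consumption = min(agent.annual_food_need, available)
    log.consumption = consumption
    log.consumption_shortfall = agent.annual_food_need - consumption
    remaining = available - consumption
    reserve = agent.annual_food_need  # one-year stock buffer
    log.surplus_consumption = min(max(0.0, remaining - reserve),
                                  0.5 * agent.annual_food_need)
    agent.food_stock = remaining - log.surplus_consumption
    return agent, log
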