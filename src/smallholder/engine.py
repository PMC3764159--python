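"""Annual simulation loop: initialization, decisions, yields, and updates.

A run covers ``years`` annual steps (default 20, the first 10 as spin-up) on
a grid partitioned into contiguous 100-ha settlement blocks, one agent per
block.  Each year every agent forms expectations and allocates labor; yields
are realized with multiplicative lognormal noise (mean 1, coefficient of
variation ``yield_cv``); stocks are updated; landscape cells degrade,
regenerate, or succeed to forest.  All randomness derives from the run seed,
so identical configurations reproduce identical results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agents as ag
from .agents import (
    ActivityAllocation,
    BehaviorParams,
    ExpectationState,
    SettlementAgent,
    allocate_labor,
    update_stocks,
)
from .landscape import (
    CULTIVATED_USES,
    GridState,
    LandUse,
    LandUseParams,
    LandscapeConfig,
    generate_topography,
    initialize_land_uses,
    step_cell,
)
from .market import CostPriceParams, MarketState, local_market

logger = logging.getLogger(__name__)

BLOCK_SIZE = 10  # cells per settlement block edge (100 ha blocks)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run."""

    population_density: float = 64.0      # people km^-2
    mi: float = 0.5                       # market influence index
    years: int = 20
    spinup_years: int = 10
    yield_cv: float = 0.10
    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    landuse: LandUseParams = field(default_factory=LandUseParams)
    costprice: CostPriceParams = field(default_factory=CostPriceParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)

    def __post_init__(self):
        if self.spinup_years >= self.years:
            raise ValueError("spinup_years must be smaller than years")
        if self.population_density < 0:
            raise ValueError("population_density must be non-negative")
        if not (0.0 <= self.mi <= 1.0):
            raise ValueError("mi must be in [0, 1]")
        if self.landscape.rows % BLOCK_SIZE or self.landscape.cols % BLOCK_SIZE:
            raise ValueError(
                f"grid dimensions must be multiples of {BLOCK_SIZE} "
                "(contiguous 100-ha settlement blocks)"
            )


@dataclass
class SimResult:
    """Trajectories of one run."""

    config: SimConfig
    market: MarketState
    agents_df: pd.DataFrame            # one row per (year, agent)
    landuse_history: np.ndarray        # (years, rows, cols) int8 land-use codes
    cultivated_history: np.ndarray     # (years, rows, cols) bool, cropped this year
    final_yield_state: np.ndarray      # (rows, cols)

    @property
    def post_spinup_years(self) -> np.ndarray:
        return np.arange(self.config.spinup_years, self.config.years)

    def post_spinup(self) -> pd.DataFrame:
        return self.agents_df[self.agents_df["year"] >= self.config.spinup_years]


def settlement_blocks(rows: int, cols: int) -> dict[int, np.ndarray]:
    """Partition the grid into contiguous BLOCK_SIZE^2-cell blocks, row-major."""
    blocks: dict[int, np.ndarray] = {}
    aid = 0
    for br in range(rows // BLOCK_SIZE):
        for bc in range(cols // BLOCK_SIZE):
            rr = np.arange(br * BLOCK_SIZE, (br + 1) * BLOCK_SIZE)
            cc = np.arange(bc * BLOCK_SIZE, (bc + 1) * BLOCK_SIZE)
            idx = (rr[:, None] * cols + cc[None, :]).ravel()
            blocks[aid] = np.sort(idx)
            aid += 1
    return blocks


def initialize(config: SimConfig) -> tuple[list[SettlementAgent], GridState, MarketState]:
    """Build agents, landscape state, and the market for one run.

    Households per settlement scale with population density (fractional
    households are allowed so density is a continuous dial); initial food and
    money stocks are per-household Table constants; risk preferences are
    drawn once per agent from Uniform(0, 1) on a stream derived from the run
    seed.
    """
    lc = config.landscape
    terrain = generate_topography(lc.rows, lc.cols, lc.seed, lc.roughness)
    market = local_market(config.mi, config.costprice)

    ss = np.random.SeedSequence(config.seed)
    rpref_rng, _ = (np.random.default_rng(s) for s in ss.spawn(2))

    blocks = settlement_blocks(lc.rows, lc.cols)
    block_area_km2 = (BLOCK_SIZE * BLOCK_SIZE) * terrain.cell_area / 100.0
    n_households = config.population_density * block_area_km2 / ag.HOUSEHOLD_SIZE

    agents: list[SettlementAgent] = []
    for aid in sorted(blocks):
        agent = SettlementAgent(
            id=aid,
            cell_indices=blocks[aid],
            n_households=n_households,
            risk_pref=float(rpref_rng.uniform(0.0, 1.0)),
            food_stock=n_households * ag.INITIAL_FOOD_PER_HOUSEHOLD,
            money_stock=n_households * ag.INITIAL_MONEY_PER_HOUSEHOLD,
            expectations=ExpectationState(
                {
                    "farmgate_price": market.farmgate_price,
                    "food_price": market.food_price,
                    "wage": market.wage,
                    "yield_factor": 1.0,
                }
            ),
        )
        agents.append(agent)

    needs = {a.id: a.annual_food_need for a in agents}
    cells = initialize_land_uses(terrain, lc, blocks, config.landuse, needs)
    grid = GridState(terrain, lc, config.landuse, cells)
    return agents, grid, market


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv <= 0 or n == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def run_simulation(config: SimConfig) -> SimResult:
    """Execute the full annual loop and record trajectories."""
    agents, grid, market = initialize(config)
    ss = np.random.SeedSequence(config.seed)
    _, yield_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    lc = config.landscape
    rows_out: list[dict] = []
    landuse_hist = np.zeros((config.years, lc.rows, lc.cols), dtype=np.int8)
    cult_hist = np.zeros((config.years, lc.rows, lc.cols), dtype=bool)

    for year in range(config.years):
        allocations: dict[int, ActivityAllocation] = {}
        for agent in agents:
            alloc = allocate_labor(
                agent,
                market,
                grid,
                behavior=config.behavior,
                yield_cv=config.yield_cv,
                prev_allocation=agent.prev_allocation,
            )
            if alloc.failed:
                logger.info("agent %d cannot meet subsistence in year %d", agent.id, year)
            allocations[agent.id] = alloc

        for agent in agents:
            alloc = allocations[agent.id]
            plan_cells = sorted(alloc.cell_plan)
            noise = _lognormal_factors(yield_rng, config.yield_cv, len(plan_cells))
            harvest = 0.0
            sales_kg = 0.0
            yf_obs = []
            for ci, eps in zip(plan_cells, noise):
                plan = alloc.cell_plan[ci]
                pot = grid.potential_yield_of(ci, plan.use)
                realized = pot * float(eps) * plan.fraction * grid.terrain.cell_area
                yf_obs.append(float(eps))
                if plan.category == "subsistence":
                    harvest += realized
                else:
                    sales_kg += realized
            input_costs = sum(p.cash_cost for p in alloc.cell_plan.values())
            transaction = (
                market.transaction_cost * alloc.nonfarm_weeks / ag.LABOR_PER_HOUSEHOLD
            )
            wage_income = alloc.nonfarm_weeks * market.wage

            agent, log = update_stocks(
                agent,
                harvest_kg=harvest + sales_kg,  # total production; sales leave the stock
                sales_kg=sales_kg,
                purchases_kg=alloc.planned_purchase_kg,
                wage_income=wage_income,
                market=market,
                input_costs=input_costs,
                transaction_costs=transaction,
                aspiration_spending=alloc.aspiration_spending,
            )
            agent.prev_allocation = alloc

            agent.expectations.observe("farmgate_price", market.farmgate_price)
            agent.expectations.observe("food_price", market.food_price)
            agent.expectations.observe("wage", market.wage)
            agent.expectations.observe(
                "yield_factor", float(np.mean(yf_obs)) if yf_obs else 1.0
            )

            rows_out.append(
                {
                    "year": year,
                    "agent": agent.id,
                    "post_spinup": year >= config.spinup_years,
                    "regime": alloc.regime.value,
                    "labor_subsistence": alloc.labor_subsistence,
                    "labor_market": alloc.labor_market,
                    "labor_nonfarm": alloc.nonfarm_weeks,
                    "labor_total": alloc.total_labor,
                    "labor_endowment": agent.labor_endowment,
                    "production_kg": harvest + sales_kg,
                    "harvest_kg": harvest,
                    "sales_kg": log.sales_kg,
                    "purchases_kg": log.purchases_kg,
                    "sales_revenue": log.sales_revenue,
                    "wage_income": log.wage_income,
                    "input_costs": log.input_costs,
                    "transaction_costs": log.transaction_costs,
                    "purchase_cost": log.purchase_cost,
                    "aspiration_spent": log.aspiration_spent,
                    "cash_required": log.input_costs
                    + log.transaction_costs
                    + log.purchase_cost,
                    "consumption": log.consumption,
                    "surplus_consumption": log.surplus_consumption,
                    "consumption_shortfall": log.consumption_shortfall,
                    "money_overdraft": log.money_overdraft,
                    "food_stock": agent.food_stock,
                    "money_stock": agent.money_stock,
                    "food_need": agent.annual_food_need,
                    "shadow_price": alloc.shadow_price
                    if math.isfinite(alloc.shadow_price)
                    else np.nan,
                    "failed": alloc.failed,
                    "farmgate_price": market.farmgate_price,
                    "food_price": market.food_price,
                    "wage": market.wage,
                }
            )

        # landscape update
        used_by_cell: dict[int, LandUse] = {}
        cultivated = np.zeros(grid.n_cells, dtype=bool)
        for alloc in allocations.values():
            for ci, plan in alloc.cell_plan.items():
                used_by_cell[ci] = plan.use
                if plan.use in CULTIVATED_USES:
                    cultivated[ci] = True
        for ci in range(grid.n_cells):
            grid.cells[ci] = step_cell(
                grid.cells[ci], used_by_cell.get(ci), grid.params, lc
            )
        landuse_hist[year] = grid.land_use_array()
        cult_hist[year] = cultivated.reshape(lc.rows, lc.cols)

    return SimResult(
        config=config,
        market=market,
        agents_df=pd.DataFrame(rows_out),
        landuse_history=landuse_hist,
        cultivated_history=cult_hist,
        final_yield_state=grid.yield_state_array(),
    )
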