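"""Pattern-oriented evaluation and genetic-algorithm search of cost/price genomes.

Three agent-level target patterns, drawn from the smallholder livelihoods
literature, define a "successful" run:

1. *Normal surplus* -- mean post-spin-up agricultural production sits between
   1.0 and 1.5 times the total subsistence requirement (little or no surplus).
2. *Minimum aspiration* -- in at least 90% of post-spin-up years the money
   stock covers the year's cash requirements (inputs, food purchases, and
   transaction costs).
3. *Consumption smoothing* -- the coefficient of variation of consumption
   possibilities (production plus income expressed in food units, relative to
   subsistence needs) stays below 0.2.

A genetic algorithm searches the cost/price coefficient vector for parameter
sets whose simulations satisfy all three patterns simultaneously.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .engine import SimConfig, SimResult, run_simulation
from .market import CostPriceParams, MarketState

#: genome fields and default search bounds
GENOME_FIELDS = ("farmgate_floor", "food_markup", "input_base",
                 "input_remote_markup", "transaction_max")
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "farmgate_floor": (0.0, 1.0),
    "food_markup": (0.0, 3.0),
    "input_base": (10.0, 300.0),
    "input_remote_markup": (0.0, 3.0),
    "transaction_max": (0.0, 20000.0),
}


@dataclass(frozen=True)
class PatternCriteria:
    """Thresholds of the three target patterns."""

    surplus_lo: float = 1.0
    surplus_hi: float = 1.5
    aspiration_frac: float = 0.9
    smoothing_cv_max: float = 0.2

    def __post_init__(self):
        if self.surplus_lo > self.surplus_hi:
            raise ValueError("surplus_lo must not exceed surplus_hi")
        if not (0.0 <= self.aspiration_frac <= 1.0):
            raise ValueError("aspiration_frac must be in [0, 1]")


def surplus_ratio(result: SimResult) -> float:
    """Mean post-spin-up ratio of total agricultural production to total need."""
    df = result.post_spinup()
    if df.empty:
        raise ValueError("post-spin-up window is empty")
    yearly = df.groupby("year").agg(prod=("production_kg", "sum"),
                                    need=("food_need", "sum"))
    if (yearly["need"] <= 0).any():
        raise ValueError("zero subsistence requirement")
    return float((yearly["prod"] / yearly["need"]).mean())


def consumption_smoothing_cv(result: SimResult, market: MarketState) -> float:
    """CV over post-spin-up years of (production + income/food price) / need."""
    df = result.post_spinup()
    years = df["year"].nunique()
    if years < 3:
        raise ValueError("need at least 3 post-spin-up years")
    yearly = df.groupby("year").agg(
        prod=("production_kg", "sum"),
        income=("wage_income", "sum"),
        revenue=("sales_revenue", "sum"),
        need=("food_need", "sum"),
    )
    d = (yearly["prod"] + (yearly["income"] + yearly["revenue"]) / market.food_price) / yearly["need"]
    mean = float(d.mean())
    if mean == 0:
        return math.inf
    return float(d.std(ddof=1) / mean)


def aspiration_fraction(result: SimResult) -> float:
    """Fraction of post-spin-up years in which money stock covers cash needs."""
    df = result.post_spinup()
    yearly = df.groupby("year").agg(money=("money_stock", "sum"),
                                    req=("cash_required", "sum"))
    return float((yearly["money"] >= yearly["req"] - 1e-9).mean())


@dataclass(frozen=True)
class PatternEvaluation:
    surplus_ratio: float
    aspiration_frac: float
    smoothing_cv: float
    surplus_ok: bool
    aspiration_ok: bool
    smoothing_ok: bool

    @property
    def success(self) -> bool:
        return self.surplus_ok and self.aspiration_ok and self.smoothing_ok

    @property
    def n_passed(self) -> int:
        return int(self.surplus_ok) + int(self.aspiration_ok) + int(self.smoothing_ok)


def evaluate_patterns(
    result: SimResult,
    criteria: PatternCriteria = PatternCriteria(),
    market: MarketState | None = None,
) -> PatternEvaluation:
    """Evaluate the three target patterns on one run (bounds are inclusive)."""
    market = market or result.market
    sr = surplus_ratio(result)
    af = aspiration_fraction(result)
    cv = consumption_smoothing_cv(result, market)
    return PatternEvaluation(
        surplus_ratio=sr,
        aspiration_frac=af,
        smoothing_cv=cv,
        surplus_ok=criteria.surplus_lo <= sr <= criteria.surplus_hi,
        aspiration_ok=af >= criteria.aspiration_frac,
        smoothing_ok=cv <= criteria.smoothing_cv_max,
    )


def pattern_fitness(ev: PatternEvaluation, criteria: PatternCriteria) -> float:
    """Patterns passed minus the normalized distance of failing metrics.

    A pure pass/fail count is flat almost everywhere; the distance term gives
    the GA a gradient toward the thresholds.
    """
    penalty = 0.0
    if not ev.surplus_ok:
        span = max(criteria.surplus_hi - criteria.surplus_lo, 1e-9)
        if ev.surplus_ratio < criteria.surplus_lo:
            penalty += min(1.0, (criteria.surplus_lo - ev.surplus_ratio) / span)
        else:
            penalty += min(1.0, (ev.surplus_ratio - criteria.surplus_hi) / span)
    if not ev.aspiration_ok:
        penalty += min(1.0, criteria.aspiration_frac - ev.aspiration_frac)
    if not ev.smoothing_ok:
        cv = ev.smoothing_cv if math.isfinite(ev.smoothing_cv) else 10.0
        penalty += min(1.0, (cv - criteria.smoothing_cv_max) / max(criteria.smoothing_cv_max, 1e-9))
    return ev.n_passed - penalty


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 32
    generations: int = 25
    tournament_size: int = 3
    crossover_rate: float = 0.7
    mutation_sd_frac: float = 0.10    # Gaussian sd as fraction of bound range
    mutation_rate: float = 0.25       # per-gene mutation probability
    max_archive: int = 60
    max_evaluations: int | None = None
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )


@dataclass
class ArchivedGenome:
    params: CostPriceParams
    evaluation: PatternEvaluation
    fitness: float


@dataclass
class GAResult:
    archive: list[ArchivedGenome]
    n_evaluations: int
    best_fitness: float


def _genome_to_params(vec: np.ndarray, template: CostPriceParams) -> CostPriceParams:
    return dataclasses.replace(
        template, **{f: float(v) for f, v in zip(GENOME_FIELDS, vec)}
    )


def ga_search(
    ga_config: GAConfig,
    sim_config_template: SimConfig,
    criteria: PatternCriteria = PatternCriteria(),
    fitness_fn=None,
) -> GAResult:
    """Evolve cost/price genomes, archiving every successful parameter set.

    Each genome is evaluated on one simulation with the template's seed held
    fixed (noise constant across genomes, keeping the search well-posed).
    ``fitness_fn(vector) -> (fitness, success)`` may replace the simulation
    (used by sanity tests on analytic landscapes).  Deterministic under
    ``ga_config.seed``; stops early once the archive is full or the
    evaluation budget is spent.
    """
    bounds = [ga_config.bounds[f] for f in GENOME_FIELDS]
    if any(hi < lo for lo, hi in bounds):
        raise ValueError("empty bounds")
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(ga_config.seed)

    def evaluate(vec: np.ndarray) -> tuple[float, bool, PatternEvaluation | None]:
        if fitness_fn is not None:
            fit, success = fitness_fn(vec)
            return fit, success, None
        params = _genome_to_params(vec, sim_config_template.costprice)
        cfg = dataclasses.replace(sim_config_template, costprice=params)
        result = run_simulation(cfg)
        ev = evaluate_patterns(result, criteria)
        return pattern_fitness(ev, criteria), ev.success, ev

    # initial population: the template genome plus uniform draws in bounds
    template_vec = np.array(
        [getattr(sim_config_template.costprice, f) for f in GENOME_FIELDS]
    )
    pop = [np.clip(template_vec, lo, hi)]
    while len(pop) < ga_config.population_size:
        pop.append(rng.uniform(lo, hi))

    archive: list[ArchivedGenome] = []
    seen: set[tuple] = set()
    n_eval = 0
    best = -math.inf

    def budget_left() -> bool:
        if ga_config.max_evaluations is None:
            return True
        return n_eval < ga_config.max_evaluations

    fitness = np.full(len(pop), -math.inf)
    for gen in range(ga_config.generations + 1):
        for i, vec in enumerate(pop):
            if not budget_left() or len(archive) >= ga_config.max_archive:
                break
            fit, success, ev = evaluate(vec)
            n_eval += 1
            fitness[i] = fit
            best = max(best, fit)
            key = tuple(np.round(vec, 10))
            if success and key not in seen:
                seen.add(key)
                archive.append(
                    ArchivedGenome(
                        params=_genome_to_params(vec, sim_config_template.costprice),
                        evaluation=ev,
                        fitness=fit,
                    )
                )
        if (
            gen == ga_config.generations
            or not budget_left()
            or len(archive) >= ga_config.max_archive
        ):
            break
        # tournament selection + blend crossover + Gaussian mutation
        new_pop: list[np.ndarray] = []
        while len(new_pop) < ga_config.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), ga_config.tournament_size)
                parents.append(pop[int(contenders[np.argmax(fitness[contenders])])])
            a, b = parents
            if rng.random() < ga_config.crossover_rate:
                w = rng.random(len(GENOME_FIELDS))
                child = w * a + (1 - w) * b
            else:
                child = a.copy()
            mutate = rng.random(len(GENOME_FIELDS)) < ga_config.mutation_rate
            noise = rng.normal(0.0, ga_config.mutation_sd_frac * (hi - lo))
            child = np.where(mutate, child + noise, child)
            new_pop.append(np.clip(child, lo, hi))
        pop = new_pop
        fitness = np.full(len(pop), -math.inf)

    return GAResult(archive=archive, n_evaluations=n_eval, best_fitness=best)
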