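"""The factorial virtual laboratory and its outcome statistics.

Runs are enumerated over population densities, market-influence settings,
and the four experimental landscapes.  Each run is summarized by the
intensity and livelihood metrics used to detect transitions:

- cropping frequency: percent of years a cell is under cultivation
  (intensive or extensive agriculture; pasture is grazing, not cropping);
- percent of allocated labor in on-farm work (subsistence + market-oriented
  agriculture + pasture), market-oriented agriculture, and non-farm wages;
- Shannon evenness of labor allocation across activities;
- surplus ratio (production over subsistence requirement).

Livelihood transitions are detected by Kruskal-Wallis tests comparing each
variable at consecutive market-influence settings, with Scheffe S multiple
comparisons of mean ranks at a 99% confidence level.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimConfig, SimResult
from .landscape import EXPERIMENTAL_LANDSCAPES

#: activity categories over which labor evenness is computed
ACTIVITY_CATEGORIES = ("subsistence_ag", "market_ag", "pasture", "nonfarm")

DEFAULT_DENSITIES = (16.0, 48.0, 80.0, 112.0, 144.0)
DEFAULT_MI_LEVELS = (0.20, 0.35, 0.50, 0.65, 0.80)


@dataclass(frozen=True)
class ExperimentGrid:
    """Axes of the factorial experiment (densities x MI levels x landscapes)."""

    densities: tuple[float, ...] = DEFAULT_DENSITIES
    mi_levels: tuple[float, ...] = DEFAULT_MI_LEVELS
    landscapes: tuple[str, ...] = tuple(EXPERIMENTAL_LANDSCAPES)
    base_config: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self):
        if not (self.densities and self.mi_levels and self.landscapes):
            raise ValueError("every experiment axis must be non-empty")
        for name in self.landscapes:
            if name not in EXPERIMENTAL_LANDSCAPES:
                raise ValueError(f"unknown landscape {name!r}")


def enumerate_grid(grid: ExperimentGrid) -> list[SimConfig]:
    """Cartesian product of the axes, density-major, then MI, then landscape."""
    configs = []
    for density, mi, name in itertools.product(
        grid.densities, grid.mi_levels, grid.landscapes
    ):
        toggles = EXPERIMENTAL_LANDSCAPES[name]
        configs.append(
            replace(
                grid.base_config,
                population_density=density,
                mi=mi,
                landscape=replace(grid.base_config.landscape, **toggles),
            )
        )
    return configs


def cropping_frequency(
    cultivated_history: np.ndarray, window: slice | None = None
) -> np.ndarray:
    """Percent of window years each cell was cultivated.

    ``cultivated_history`` is a (years, rows, cols) boolean array (True when
    the cell was cropped that year); ``window`` selects years (default all).
    """
    hist = cultivated_history if window is None else cultivated_history[window]
    if hist.shape[0] == 0:
        raise ValueError("window must contain at least one year")
    return 100.0 * hist.mean(axis=0)


def landscape_cropping_frequency(result: SimResult, post_spinup: bool = True) -> float:
    """Area-mean cropping frequency (%) over the post-spin-up window."""
    window = slice(result.config.spinup_years, None) if post_spinup else None
    return float(cropping_frequency(result.cultivated_history, window).mean())


def evenness_index(labor_shares) -> float:
    """Shannon evenness H / ln(K) of labor over the activity categories.

    1 for equal shares, 0 when a single activity holds all labor; invariant
    to permutation and to rescaling of the shares.
    """
    p = np.asarray(labor_shares, dtype=float)
    if np.any(p < 0):
        raise ValueError("labor shares must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValueError("labor shares must not all be zero")
    p = p / total
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / math.log(len(p))


@dataclass(frozen=True)
class RunMetrics:
    """Summary metrics of one simulation run (post-spin-up window)."""

    cropping_frequency_mean: float    # % of cell-years cultivated
    cropping_frequency_median: float  # median per-cell %
    pct_farm_labor: float
    pct_market_labor: float
    pct_nonfarm_labor: float
    surplus_ratio: float
    evenness: float
    total_production_kg: float


def run_metrics(result: SimResult) -> RunMetrics:
    """Compute the outcome metrics of one run over its post-spin-up years."""
    from .calibration import surplus_ratio as _surplus

    df = result.post_spinup()
    window = slice(result.config.spinup_years, None)
    freq = cropping_frequency(result.cultivated_history, window)

    # labor_subsistence covers all own-consumption land work (incl. grazing),
    # labor_market all market-oriented land work; the pasture evenness
    # category is zero unless grazing is tracked separately
    sub = float(df["labor_subsistence"].sum())
    mkt = float(df["labor_market"].sum())
    nonfarm = float(df["labor_nonfarm"].sum())
    total = sub + mkt + nonfarm
    if total <= 0:
        pct_farm = pct_mkt = pct_nonfarm = 0.0
        evenness = 0.0
    else:
        pct_farm = 100.0 * (sub + mkt) / total
        pct_mkt = 100.0 * mkt / total
        pct_nonfarm = 100.0 * nonfarm / total
        evenness = evenness_index([sub, mkt, 0.0, nonfarm])
    return RunMetrics(
        cropping_frequency_mean=float(freq.mean()),
        cropping_frequency_median=float(np.median(freq)),
        pct_farm_labor=pct_farm,
        pct_market_labor=pct_mkt,
        pct_nonfarm_labor=pct_nonfarm,
        surplus_ratio=_surplus(result),
        evenness=evenness,
        total_production_kg=float(df["production_kg"].sum()),
    )


def metrics_row(result: SimResult, landscape_name: str | None = None) -> dict:
    """One metrics.csv row: experiment coordinates plus RunMetrics fields."""
    m = run_metrics(result)
    row = {
        "density": result.config.population_density,
        "mi": result.config.mi,
        "landscape": landscape_name or "",
        "seed": result.config.seed,
    }
    row.update(dataclasses_asdict_flat(m))
    return row


def dataclasses_asdict_flat(m: RunMetrics) -> dict:
    return {
        "cropping_frequency_mean": m.cropping_frequency_mean,
        "cropping_frequency_median": m.cropping_frequency_median,
        "pct_farm_labor": m.pct_farm_labor,
        "pct_market_labor": m.pct_market_labor,
        "pct_nonfarm_labor": m.pct_nonfarm_labor,
        "surplus_ratio": m.surplus_ratio,
        "evenness": m.evenness,
        "total_production_kg": m.total_production_kg,
    }


# ---------------------------------------------------------------------------
# rank statistics


def kruskal_wallis_pair(values_a, values_b) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square (1 df) p-value.

    Two identical groups give (0, 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    ra = ranks[: len(a)]
    rb = ranks[len(a):]
    h = (12.0 / (n * (n + 1))) * (
        len(a) * (ra.mean() - (n + 1) / 2.0) ** 2
        + len(b) * (rb.mean() - (n + 1) / 2.0) ** 2
    )
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if correction == 0.0:  # all values identical
        return 0.0, 1.0
    h /= correction
    return float(h), float(stats.chi2.sf(h, df=1))


@dataclass(frozen=True)
class PairComparison:
    """Scheffe S comparison of mean ranks for one consecutive MI pair."""

    level_a: float
    level_b: float
    estimate: float          # mean rank(b) - mean rank(a)
    ci_lo: float
    ci_hi: float
    significant: bool
    median_a: float
    median_b: float

    @property
    def direction(self) -> str:
        if not self.significant:
            return "none"
        return "increase" if self.median_b > self.median_a else "decrease"


@dataclass(frozen=True)
class TransitionTestResult:
    variable: str
    comparisons: tuple[PairComparison, ...]


def scheffe_rank_comparison(
    values_by_level: dict[float, np.ndarray], alpha: float = 0.01,
    variable: str = "",
) -> TransitionTestResult:
    """Scheffe S multiple comparisons of mean ranks across MI levels.

    All observations are ranked jointly; for each consecutive pair of levels
    the estimate is the difference of mean ranks and the half-width is
    ``sqrt((k-1) F_{alpha; k-1, N-k}) x SE`` with the standard error from the
    rank-based one-way ANOVA mean square error.  A confidence interval that
    excludes zero flags a significant shift.
    """
    levels = sorted(values_by_level)
    if len(levels) < 2:
        raise ValueError("need at least two MI levels")
    groups = [np.asarray(values_by_level[lv], dtype=float) for lv in levels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each level needs at least 2 runs")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    k = len(groups)
    ranks = stats.rankdata(pooled)
    rank_groups = []
    start = 0
    for g in groups:
        rank_groups.append(ranks[start: start + len(g)])
        start += len(g)
    grand = ranks.mean()
    ss_between = sum(len(r) * (r.mean() - grand) ** 2 for r in rank_groups)
    ss_total = ((ranks - grand) ** 2).sum()
    df_error = n_total - k
    mse = (ss_total - ss_between) / df_error if df_error > 0 else 0.0
    crit = math.sqrt((k - 1) * stats.f.ppf(1.0 - alpha, k - 1, df_error))

    comparisons = []
    for i in range(k - 1):
        ra, rb = rank_groups[i], rank_groups[i + 1]
        est = float(rb.mean() - ra.mean())
        se = math.sqrt(mse * (1.0 / len(ra) + 1.0 / len(rb)))
        half = crit * se
        comparisons.append(
            PairComparison(
                level_a=levels[i],
                level_b=levels[i + 1],
                estimate=est,
                ci_lo=est - half,
                ci_hi=est + half,
                significant=not (est - half <= 0.0 <= est + half),
                median_a=float(np.median(groups[i])),
                median_b=float(np.median(groups[i + 1])),
            )
        )
    return TransitionTestResult(variable=variable, comparisons=tuple(comparisons))


#: metrics.csv columns analyzed for livelihood transitions
TRANSITION_VARIABLES = (
    "pct_farm_labor",
    "pct_market_labor",
    "surplus_ratio",
    "evenness",
)


def detect_transitions(
    metrics_table: pd.DataFrame,
    variables: tuple[str, ...] = TRANSITION_VARIABLES,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Label significant shifts of each variable across consecutive MI levels.

    ``metrics_table`` needs an ``mi`` column plus the variable columns (one
    row per run; runs are pooled over densities/landscapes/seeds).  Returns a
    long table with one row per (variable, MI boundary).
    """
    rows = []
    for var in variables:
        by_level = {
            float(mi): g[var].to_numpy() for mi, g in metrics_table.groupby("mi")
        }
        if len(by_level) < 2:
            continue
        res = scheffe_rank_comparison(by_level, alpha=alpha, variable=var)
        for c in res.comparisons:
            rows.append(
                {
                    "variable": var,
                    "mi_from": c.level_a,
                    "mi_to": c.level_b,
                    "mean_rank_diff": c.estimate,
                    "ci_lo": c.ci_lo,
                    "ci_hi": c.ci_hi,
                    "significant": c.significant,
                    "direction": c.direction,
                    "median_from": c.median_a,
                    "median_to": c.median_b,
                }
            )
    return pd.DataFrame(rows)
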