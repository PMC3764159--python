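"""Artificial terrain, land suitability, and per-cell land-use dynamics.

The simulated world is a rectangular grid of 1-ha cells.  Each cell carries an
elevation, a slope (percent rise per cell width, used as a proxy for soil
suitability), a land use drawn from six categories, and a ``yield_state`` in
[0, 1] expressing the fraction of pristine yield potential that remains after
degradation.  Cultivation of extensive agriculture or grazing degrades a cell;
fallowing regenerates it at the rate of the most recent productive use, and
long-fallowed cells succeed to forest.

Potential yield composes multiplicatively: a base yield per productive use, a
slope-class suitability multiplier (when the slope constraint is on), a flat
precipitation reduction (when the precipitation constraint is on), and the
cell's yield state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage


class LandUse(IntEnum):
    """Six land-use categories; the integer codes are used in .asc rasters."""

    INTENSIVE_AG = 1
    EXTENSIVE_AG = 2
    PASTURE = 3
    FOREST = 4
    FALLOW = 5
    DWELLING = 6


PRODUCTIVE_USES = (LandUse.INTENSIVE_AG, LandUse.EXTENSIVE_AG, LandUse.PASTURE)
#: uses counted as "cropping" in the cropping-frequency intensity metric
CULTIVATED_USES = (LandUse.INTENSIVE_AG, LandUse.EXTENSIVE_AG)

#: GAEZ-style slope suitability classes: (upper bound of slope %, multiplier).
DEFAULT_SLOPE_CLASSES: tuple[tuple[float, float], ...] = (
    (2.0, 1.00),
    (5.0, 0.90),
    (8.0, 0.75),
    (16.0, 0.50),
    (30.0, 0.25),
    (math.inf, 0.05),
)

#: metres per cell edge (1 ha square cells)
CELL_WIDTH_M = 100.0


@dataclass(frozen=True)
class TerrainGrid:
    """Elevation field and derived slope, in percent rise per cell width."""

    elevation: np.ndarray
    slope_pct: np.ndarray
    rows: int
    cols: int
    cell_area: float = 1.0  # hectares


@dataclass(frozen=True)
class LandUseParams:
    """Biophysical parameters of the three productive uses.

    Yields are kg grain-equivalent per hectare per year on pristine land;
    degradation/regeneration rates are fractions of pristine yield potential
    per year.  All product prices are equal, which controls for
    commodity-differentiated price effects.  Labor costs are person-weeks per
    hectare per year: a maintenance cost for keeping a cell in a productive
    use, plus a conversion adder depending on the prior use.
    """

    base_yield: dict[LandUse, float] = field(
        default_factory=lambda: {
            LandUse.INTENSIVE_AG: 3500.0,
            LandUse.EXTENSIVE_AG: 2700.0,
            LandUse.PASTURE: 1700.0,
        }
    )
    degradation_rate: dict[LandUse, float] = field(
        default_factory=lambda: {
            LandUse.INTENSIVE_AG: 0.0,
            LandUse.EXTENSIVE_AG: 0.25,
            LandUse.PASTURE: 0.18,
        }
    )
    regeneration_rate: dict[LandUse, float] = field(
        default_factory=lambda: {
            LandUse.INTENSIVE_AG: 0.0,
            LandUse.EXTENSIVE_AG: 0.04,
            LandUse.PASTURE: 0.5,
        }
    )
    price: float = 0.13  # $ per kg, identical across products
    maintenance_labor: dict[LandUse, float] = field(
        default_factory=lambda: {
            LandUse.INTENSIVE_AG: 10.0,
            LandUse.EXTENSIVE_AG: 6.0,
            LandUse.PASTURE: 5.0,
        }
    )
    conversion_labor: dict[LandUse, float] = field(
        default_factory=lambda: {
            LandUse.FOREST: 4.0,   # clearing
            LandUse.FALLOW: 2.0,
            LandUse.INTENSIVE_AG: 1.0,
            LandUse.EXTENSIVE_AG: 1.0,
            LandUse.PASTURE: 1.0,
            LandUse.DWELLING: 0.0,
        }
    )
    #: regeneration applied to forest cells (succession continues to build soil)
    forest_regeneration: float = 0.04

    def labor_cost(self, from_use: LandUse, to_use: LandUse) -> float:
        """Person-weeks ha^-1 yr^-1 to convert ``from_use`` to ``to_use`` and work it."""
        if to_use not in self.maintenance_labor:
            raise ValueError(f"{to_use!r} is not a productive use")
        cost = self.maintenance_labor[to_use]
        if from_use != to_use:
            cost += self.conversion_labor.get(from_use, 1.0)
        return cost


@dataclass(frozen=True)
class LandscapeConfig:
    """Grid geometry, terrain seed, and the on/off environmental constraints.

    The four experimental landscapes are the four combinations of
    ``slope_constraint_on`` and ``precip_constraint_on``.
    """

    rows: int = 100
    cols: int = 100
    seed: int = 0
    roughness: float = 0.25
    slope_constraint_on: bool = True
    precip_constraint_on: bool = True
    precip_reduction: float = 0.5
    fallow_to_forest_years: int = 10
    slope_classes: tuple[tuple[float, float], ...] = DEFAULT_SLOPE_CLASSES

    def __post_init__(self):
        if not (0.0 <= self.precip_reduction <= 1.0):
            raise ValueError("precip_reduction must be in [0, 1]")


#: the four named experimental landscapes
EXPERIMENTAL_LANDSCAPES: dict[str, dict[str, bool]] = {
    "baseline": {"slope_constraint_on": True, "precip_constraint_on": True},
    "slope_only": {"slope_constraint_on": True, "precip_constraint_on": False},
    "precip_only": {"slope_constraint_on": False, "precip_constraint_on": True},
    "neutral": {"slope_constraint_on": False, "precip_constraint_on": False},
}


@dataclass
class CellState:
    """State of a single 1-ha cell."""

    land_use: LandUse = LandUse.FOREST
    yield_state: float = 1.0
    years_fallow: int = 0
    owner: int = -1
    #: most recent productive use; sets the fallow regeneration rate
    prev_productive_use: LandUse = LandUse.EXTENSIVE_AG


def generate_topography(
    rows: int, cols: int, seed: int, roughness: float = 0.25
) -> TerrainGrid:
    """Generate a smooth pseudo-random elevation field and its slope map.

    Gaussian white noise is smoothed with a Gaussian kernel (correlation
    length ~3 cells), normalized to unit standard deviation, and scaled by
    ``roughness``; elevation is expressed in cell-width units so the slope in
    percent is simply 100 x the finite-difference gradient magnitude.
    ``roughness=0`` yields a flat field.  Identical arguments give
    bit-identical grids.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must each be at least 2")
    if roughness < 0:
        raise ValueError("roughness must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((rows, cols))
    smooth = ndimage.gaussian_filter(noise, sigma=3.0, mode="wrap")
    sd = smooth.std()
    if sd > 0 and roughness > 0:
        elevation = smooth * (roughness / sd)
    else:
        elevation = np.zeros((rows, cols))
    slope_pct = slope_from_elevation(elevation)
    return TerrainGrid(elevation=elevation, slope_pct=slope_pct, rows=rows, cols=cols)


def slope_from_elevation(elevation: np.ndarray) -> np.ndarray:
    """Percent slope by central finite differences (elevation in cell-width units)."""
    gy, gx = np.gradient(elevation)
    return np.hypot(gy, gx) * 100.0


def slope_suitability(
    slope_pct,
    slope_classes: tuple[tuple[float, float], ...] = DEFAULT_SLOPE_CLASSES,
):
    """Piecewise-constant, non-increasing suitability multiplier in [0, 1].

    Accepts a scalar or array of non-negative percent slopes.
    """
    arr = np.asarray(slope_pct, dtype=float)
    if np.any(arr < 0):
        raise ValueError("slope_pct must be non-negative")
    bounds = np.array([b for b, _ in slope_classes])
    mults = np.array([m for _, m in slope_classes])
    idx = np.searchsorted(bounds, arr, side="left")
    out = mults[np.minimum(idx, len(mults) - 1)]
    if np.isscalar(slope_pct) or np.ndim(slope_pct) == 0:
        return float(out)
    return out


def environment_multiplier(
    slope_pct, config: LandscapeConfig
):
    """Combined slope x precipitation multiplier for the configured landscape."""
    mult = np.ones_like(np.asarray(slope_pct, dtype=float))
    if config.slope_constraint_on:
        mult = mult * slope_suitability(slope_pct, config.slope_classes)
    if config.precip_constraint_on:
        mult = mult * (1.0 - config.precip_reduction)
    if np.ndim(slope_pct) == 0:
        return float(mult)
    return mult


def potential_yield(
    cell: CellState,
    use: LandUse,
    slope_pct: float,
    config: LandscapeConfig,
    params: LandUseParams,
) -> float:
    """Potential yield (kg ha^-1) of ``use`` on ``cell`` under the landscape constraints.

    Non-productive uses yield zero.  Constraints compose multiplicatively with
    the cell's degradation state.  Intensive agriculture uses external inputs
    (fertilizer, irrigation, land improvement) to maintain productivity, so
    its potential yield does not scale with accumulated degradation.
    """
    if use not in params.base_yield:
        return 0.0
    state = 1.0 if use == LandUse.INTENSIVE_AG else cell.yield_state
    return params.base_yield[use] * environment_multiplier(slope_pct, config) * state


def step_cell(
    cell: CellState,
    used_this_year: LandUse | None,
    params: LandUseParams,
    config: LandscapeConfig,
) -> CellState:
    """Advance one cell by one year of degradation/regeneration/succession.

    ``used_this_year`` is the productive use worked on the cell this year, or
    ``None`` if the cell was left idle (productive cells left idle become
    fallow).  Dwellings are inert.
    """
    if cell.land_use == LandUse.DWELLING:
        return replace(cell)
    if used_this_year is not None:
        rate = params.degradation_rate[used_this_year]
        return replace(
            cell,
            land_use=used_this_year,
            yield_state=max(0.0, cell.yield_state - rate),
            years_fallow=0,
            prev_productive_use=used_this_year,
        )
    # idle: forest stays forest, everything else is (or becomes) fallow
    if cell.land_use == LandUse.FOREST:
        return replace(
            cell,
            yield_state=min(1.0, cell.yield_state + params.forest_regeneration),
            years_fallow=0,
        )
    regen = params.regeneration_rate.get(cell.prev_productive_use, 0.0)
    years = cell.years_fallow + 1
    new_use = (
        LandUse.FOREST if years >= config.fallow_to_forest_years else LandUse.FALLOW
    )
    return replace(
        cell,
        land_use=new_use,
        yield_state=min(1.0, cell.yield_state + regen),
        years_fallow=0 if new_use == LandUse.FOREST else years,
    )


class GridState:
    """Terrain plus the mutable per-cell state of the whole landscape.

    Cells are indexed flat, row-major.  Caches the environmental multiplier
    (slope x precipitation), which is constant within a run.
    """

    def __init__(
        self,
        terrain: TerrainGrid,
        config: LandscapeConfig,
        params: LandUseParams,
        cells: list[CellState],
    ):
        self.terrain = terrain
        self.config = config
        self.params = params
        self.cells = cells
        self.slope_flat = terrain.slope_pct.ravel()
        self.env_mult = np.asarray(
            environment_multiplier(self.slope_flat, config), dtype=float
        )
        if self.env_mult.ndim == 0:
            self.env_mult = np.full(terrain.rows * terrain.cols, float(self.env_mult))

    @property
    def n_cells(self) -> int:
        return self.terrain.rows * self.terrain.cols

    def land_use_array(self) -> np.ndarray:
        return np.array([c.land_use for c in self.cells], dtype=np.int8).reshape(
            self.terrain.rows, self.terrain.cols
        )

    def yield_state_array(self) -> np.ndarray:
        return np.array([c.yield_state for c in self.cells], dtype=float).reshape(
            self.terrain.rows, self.terrain.cols
        )

    def potential_yield_of(self, idx: int, use: LandUse) -> float:
        """Potential yield (kg ha^-1) of ``use`` on flat-index cell ``idx``."""
        if use not in self.params.base_yield:
            return 0.0
        state = 1.0 if use == LandUse.INTENSIVE_AG else self.cells[idx].yield_state
        return self.params.base_yield[use] * self.env_mult[idx] * state


def initialize_land_uses(
    terrain: TerrainGrid,
    config: LandscapeConfig,
    agent_cells: dict[int, np.ndarray],
    params: LandUseParams,
    food_need_per_agent: dict[int, float],
) -> list[CellState]:
    """Assign initial land uses per settlement according to suitability.

    Each settlement receives one dwelling on its lowest-index cell; its most
    suitable cells are put under extensive agriculture until expected yields
    cover the settlement's first-year subsistence need; the remainder is
    forest.  Ties between equally suitable cells go to the lowest cell index.
    """
    n = terrain.rows * terrain.cols
    slope_flat = terrain.slope_pct.ravel()
    cells: list[CellState] = [CellState() for _ in range(n)]
    for agent_id, idxs in agent_cells.items():
        idxs = np.asarray(idxs)
        if idxs.size == 0:
            raise ValueError(f"settlement {agent_id} owns zero cells")
        for i in idxs:
            cells[i].owner = int(agent_id)
        dwelling = int(idxs.min())
        cells[dwelling].land_use = LandUse.DWELLING
        need = food_need_per_agent.get(agent_id, 0.0)
        if need <= 0:
            continue
        candidates = idxs[idxs != dwelling]
        yields = params.base_yield[LandUse.EXTENSIVE_AG] * environment_multiplier(
            slope_flat[candidates], config
        )
        order = np.lexsort((candidates, -yields))  # best yield first, lowest index ties
        covered = 0.0
        for j in order:
            if covered >= need:
                break
            ci = int(candidates[j])
            if yields[j] <= 0:
                break
            cells[ci].land_use = LandUse.EXTENSIVE_AG
            cells[ci].prev_productive_use = LandUse.EXTENSIVE_AG
            covered += float(yields[j]) * terrain.cell_area
    return cells
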