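"""Configuration files, fixtures, and run outputs.

Runs are configured with a strict YAML schema (unknown keys are typos and
are rejected; every violation is reported, not just the first).  Outputs are
plain text: RFC-4180 CSV tables, ESRI ASCII grid rasters, and a JSON
manifest with configuration echo and file checksums sufficient to reproduce
a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agents import BehaviorParams, ExpectationState, SettlementAgent
from .engine import SimConfig, SimResult
from .landscape import (
    CellState,
    EXPERIMENTAL_LANDSCAPES,
    GridState,
    LandUse,
    LandUseParams,
    LandscapeConfig,
    generate_topography,
)
from .market import CostPriceParams, local_market

NODATA = -9999


class ConfigError(ValueError):
    """Raised with the full list of configuration violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def _num(x):
    return isinstance(x, (int, float)) and not isinstance(x, bool)


#: section -> key -> (validator, message)
_SCHEMA = {
    "simulation": {
        "population_density": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "mi": (lambda v: _num(v) and 0 <= v <= 1, "must be a number in [0, 1]"),
        "years": (lambda v: isinstance(v, int) and v > 0, "must be a positive integer"),
        "spinup_years": (lambda v: isinstance(v, int) and v >= 0, "must be an integer >= 0"),
        "yield_cv": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "seed": (lambda v: isinstance(v, int), "must be an integer"),
    },
    "landscape": {
        "name": (lambda v: v in EXPERIMENTAL_LANDSCAPES,
                 f"must be one of {sorted(EXPERIMENTAL_LANDSCAPES)}"),
        "rows": (lambda v: isinstance(v, int) and v >= 10, "must be an integer >= 10"),
        "cols": (lambda v: isinstance(v, int) and v >= 10, "must be an integer >= 10"),
        "seed": (lambda v: isinstance(v, int), "must be an integer"),
        "roughness": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "slope_constraint_on": (lambda v: isinstance(v, bool), "must be a boolean"),
        "precip_constraint_on": (lambda v: isinstance(v, bool), "must be a boolean"),
        "precip_reduction": (lambda v: _num(v) and 0 <= v <= 1, "must be in [0, 1]"),
        "fallow_to_forest_years": (lambda v: isinstance(v, int) and v > 0,
                                   "must be a positive integer"),
    },
    "costprice": {
        "global_price": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "wage_ceiling": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "farmgate_floor": (lambda v: _num(v) and 0 <= v <= 1, "must be in [0, 1]"),
        "food_markup": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "input_base": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "input_remote_markup": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "transaction_max": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
    },
    "behavior": {
        "lambda_0": (lambda v: _num(v) and 0 <= v <= 1, "must be in [0, 1]"),
        "lambda_min": (lambda v: _num(v) and 0 <= v <= 1, "must be in [0, 1]"),
        "aspiration_exponent": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "aspiration_per_household": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "food_reserve_years": (lambda v: _num(v) and v >= 0, "must be a number >= 0"),
        "sales_income_safety": (lambda v: _num(v) and 0 <= v <= 1, "must be in [0, 1]"),
    },
}


def load_config(path) -> SimConfig:
    """Load and validate a YAML run configuration.

    Omitted fields take the model defaults (Table constants); unknown
    sections or keys and out-of-range values are all reported together.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> SimConfig:
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping of sections"])
    for section in raw:
        if section not in _SCHEMA:
            errors.append(f"unknown section '{section}'")
    clean: dict[str, dict] = {}
    for section, keys in _SCHEMA.items():
        sub = raw.get(section, {}) or {}
        if not isinstance(sub, dict):
            errors.append(f"section '{section}' must be a mapping")
            continue
        clean[section] = {}
        for key, value in sub.items():
            if key not in keys:
                errors.append(f"unknown key '{section}.{key}'")
                continue
            check, msg = keys[key]
            if not check(value):
                errors.append(f"'{section}.{key}' = {value!r}: {msg}")
            else:
                clean[section][key] = value
    if errors:
        raise ConfigError(errors)

    land_kwargs = dict(clean.get("landscape", {}))
    name = land_kwargs.pop("name", None)
    if name is not None:
        land_kwargs.update(EXPERIMENTAL_LANDSCAPES[name])
    try:
        config = SimConfig(
            landscape=LandscapeConfig(**land_kwargs),
            costprice=CostPriceParams(**clean.get("costprice", {})),
            behavior=BehaviorParams(**clean.get("behavior", {})),
            **clean.get("simulation", {}),
        )
    except ValueError as exc:
        raise ConfigError([str(exc)]) from exc
    return config


def config_to_dict(config: SimConfig) -> dict:
    """Inverse of :func:`config_from_dict` (round-trips exactly)."""
    return {
        "simulation": {
            "population_density": config.population_density,
            "mi": config.mi,
            "years": config.years,
            "spinup_years": config.spinup_years,
            "yield_cv": config.yield_cv,
            "seed": config.seed,
        },
        "landscape": {
            "rows": config.landscape.rows,
            "cols": config.landscape.cols,
            "seed": config.landscape.seed,
            "roughness": config.landscape.roughness,
            "slope_constraint_on": config.landscape.slope_constraint_on,
            "precip_constraint_on": config.landscape.precip_constraint_on,
            "precip_reduction": config.landscape.precip_reduction,
            "fallow_to_forest_years": config.landscape.fallow_to_forest_years,
        },
        "costprice": {
            f.name: getattr(config.costprice, f.name)
            for f in dataclasses.fields(config.costprice)
        },
        "behavior": {
            f.name: getattr(config.behavior, f.name)
            for f in dataclasses.fields(config.behavior)
        },
    }


def save_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_NAMES = ("flat_2agent", "hill_4agent", "toy_3cell")


def make_fixture(name: str) -> dict:
    """Deterministic miniature scenarios used throughout the test-suite.

    ``flat_2agent``: 10x20 flat neutral landscape, 2 settlements, no yield
    noise.  ``hill_4agent``: 20x20 baseline landscape with terrain.
    ``toy_3cell``: a 3-cell allocation instance with its optimum precomputed
    by hand (one pristine and two degraded extensive cells, 20 person-weeks).
    """
    if name == "flat_2agent":
        return {
            "config": SimConfig(
                population_density=64.0,
                mi=0.5,
                yield_cv=0.0,
                seed=1,
                landscape=LandscapeConfig(
                    rows=10, cols=20, seed=1, roughness=0.0,
                    slope_constraint_on=False, precip_constraint_on=False,
                ),
            )
        }
    if name == "hill_4agent":
        return {
            "config": SimConfig(
                population_density=64.0,
                mi=0.5,
                yield_cv=0.10,
                seed=7,
                landscape=LandscapeConfig(rows=20, cols=20, seed=7),
            )
        }
    if name == "toy_3cell":
        return _toy_3cell()
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def _toy_3cell() -> dict:
    """Three extensive cells (yield states 1.0, 0.75, 0.5) and 20 person-weeks.

    The agent's food target equals its one-year need (stock holds exactly the
    reserve), so the optimum cultivates a 0.19907 fraction of the pristine
    cell (537.5 kg at 2700 kg/ha) and works 0.4033 person-weeks off-farm to
    cover the aspiration cash target of 18.57 $ at the net wage 46.04 $/pw.
    """
    lc = LandscapeConfig(rows=10, cols=10, seed=0, roughness=0.0,
                         slope_constraint_on=False, precip_constraint_on=False)
    terrain = generate_topography(lc.rows, lc.cols, lc.seed, lc.roughness)
    params = LandUseParams()
    cells = [CellState() for _ in range(terrain.rows * terrain.cols)]
    for idx, ys in zip((0, 1, 2), (1.0, 0.75, 0.5)):
        cells[idx] = CellState(
            land_use=LandUse.EXTENSIVE_AG, yield_state=ys, owner=0,
            prev_productive_use=LandUse.EXTENSIVE_AG,
        )
    grid = GridState(terrain, lc, params, cells)
    n_households = 20.0 / 96.0
    market = local_market(0.5, CostPriceParams())
    agent = SettlementAgent(
        id=0,
        cell_indices=np.array([0, 1, 2]),
        n_households=n_households,
        risk_pref=0.0,
        food_stock=n_households * 2580.0,     # exactly the one-year reserve
        money_stock=n_households * 1426.0,    # exactly the money reserve
        expectations=ExpectationState(
            {
                "farmgate_price": market.farmgate_price,
                "food_price": market.food_price,
                "wage": market.wage,
                "yield_factor": 1.0,
            }
        ),
    )
    behavior = BehaviorParams()
    need = agent.annual_food_need
    w_net = market.wage - market.transaction_cost / 96.0
    aspiration = (
        n_households
        * behavior.aspiration_per_household
        * market.mi**behavior.aspiration_exponent
    )
    return {
        "grid": grid,
        "agent": agent,
        "market": market,
        "behavior": behavior,
        "expected": {
            "food_target_kg": need,
            "subsistence_cell": 0,
            "subsistence_fraction": need / 2700.0,
            "labor_subsistence": 6.0 * need / 2700.0,
            "net_wage": w_net,
            "cash_target": aspiration,
            "nonfarm_weeks": aspiration / w_net,
        },
    }


# ---------------------------------------------------------------------------
# output files


def write_ascii_grid(path, array: np.ndarray, cellsize: float = 100.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (.asc), NODATA_value -9999."""
    arr = np.asarray(array)
    rows, cols = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\nnrows {rows}\n")
        fh.write(f"xllcorner 0.0\nyllcorner 0.0\ncellsize {cellsize}\n")
        fh.write(f"NODATA_value {NODATA}\n")
        for row in arr:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path) -> np.ndarray:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    lines = Path(path).read_text().splitlines()
    header = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        }:
            header[parts[0].lower()] = float(parts[1])
            data_start = i + 1
        else:
            break
    arr = np.array([[float(v) for v in line.split()] for line in lines[data_start:]])
    assert arr.shape == (int(header["nrows"]), int(header["ncols"]))
    return arr


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: SimResult, metrics: pd.DataFrame | None, out_dir) -> dict:
    """Write trajectories.csv, cells.csv, metrics.csv, rasters, manifest.json.

    Returns the manifest.  Numeric CSV values use 6 significant digits.
    """
    from .experiments import cropping_frequency

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    traj = out / "trajectories.csv"
    result.agents_df.to_csv(traj, index=False, float_format="%.6g")
    files.append(traj)

    lc = result.config.landscape
    window = slice(result.config.spinup_years, None)
    freq = cropping_frequency(result.cultivated_history, window)
    rows, cols = np.unravel_index(
        np.arange(lc.rows * lc.cols), (lc.rows, lc.cols)
    )
    cells = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "final_land_use": result.landuse_history[-1].ravel(),
            "final_yield_state": result.final_yield_state.ravel(),
            "cropping_frequency_pct": freq.ravel(),
        }
    )
    cells_path = out / "cells.csv"
    cells.to_csv(cells_path, index=False, float_format="%.6g")
    files.append(cells_path)

    if metrics is not None:
        mpath = out / "metrics.csv"
        metrics.to_csv(mpath, index=False, float_format="%.6g")
        files.append(mpath)

    final_year = result.config.years - 1
    lu_path = out / f"landuse_year{final_year:02d}.asc"
    write_ascii_grid(lu_path, result.landuse_history[-1])
    files.append(lu_path)
    cf_path = out / "cropping_frequency.asc"
    write_ascii_grid(cf_path, freq)
    files.append(cf_path)

    manifest = {
        "config": config_to_dict(result.config),
        "seed": result.config.seed,
        "version": __version__,
        "created_unix": int(time.time()),
        "files": {p.name: _sha256(p) for p in files},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return manifest
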