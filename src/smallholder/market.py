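"""Market influence and the local prices, costs, and wages it induces.

A single global market influence (MI) index in [0, 1] summarizes physical
access to markets and purchasing power.  Five linear-in-MI functions map the
index to the local farm-gate price, consumer food price, farm input cost,
non-farm wage, and the transaction cost of securing non-farm employment.  At
MI = 1 the farm-gate and food prices both equal the global commodity price,
the wage reaches its ceiling (U.S. minimum wage at 40 h per person-week), and
transaction costs vanish; as MI falls toward 0 the farm-gate/food price gap
widens, inputs grow dearer, wages fall, and transaction frictions grow.

An agent's market-participation regime follows from the position of its
shadow price (internal unit cost of self-provisioned food) relative to the
farm-gate and food prices, after de Janvry: a shadow price below the
farm-gate price makes market-oriented production profitable (mixed regime);
between farm-gate and food price the agent sits in the autarkic price gap
(subsistence regime); above the food price, buying food and selling labor
dominates self-provisioning (sell-and-buy regime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum


@dataclass(frozen=True)
class CostPriceParams:
    """Coefficients of the five MI-to-local cost/price functions.

    This vector is the genome searched by the calibration GA.  ``tau_0`` is
    the transaction cost, in dollars per household-year, of locating and
    maintaining non-farm employment for a fully isolated settlement (MI = 0).
    """

    global_price: float = 0.13          # $ kg^-1, 5-year average farm wheat price
    wage_ceiling: float = 290.0         # $ per person-week (7.25 $/h x 40 h)
    farmgate_floor: float = 0.3         # b_f: farm-gate price fraction at MI=0
    food_markup: float = 1.0            # m_w: food price markup at MI=0
    input_base: float = 100.0           # c_0: $ ha^-1 input cost at MI=1
    input_remote_markup: float = 1.0    # c_1: input cost markup at MI=0
    transaction_max: float = 19000.0    # tau_0: $ per household-year at MI=0

    def __post_init__(self):
        for name in (
            "global_price", "wage_ceiling", "food_markup",
            "input_base", "input_remote_markup", "transaction_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.farmgate_floor <= 1.0):
            raise ValueError("farmgate_floor must be in [0, 1]")


@dataclass(frozen=True)
class MarketState:
    """Local prices/costs induced by one MI setting."""

    mi: float
    farmgate_price: float       # $ kg^-1 received by the farmer
    food_price: float           # $ kg^-1 paid for food
    input_cost: float           # $ ha^-1 yr^-1 for intensive-agriculture inputs
    wage: float                 # $ per person-week of non-farm work
    transaction_cost: float     # $ per household-year of non-farm engagement


class Regime(Enum):
    """Market-participation regime from the shadow-price comparison."""

    SUBSISTENCE_GAP = "subsistence_gap"
    MIXED = "mixed"
    SELL_AND_BUY = "sell_and_buy"


def local_market(mi: float, params: CostPriceParams) -> MarketState:
    """Evaluate the five linear cost/price functions at one MI value."""
    if not (0.0 <= mi <= 1.0):
        raise ValueError(f"mi must be in [0, 1], got {mi}")
    p = params.global_price
    return MarketState(
        mi=mi,
        farmgate_price=p * (params.farmgate_floor + (1.0 - params.farmgate_floor) * mi),
        food_price=p * (1.0 + params.food_markup * (1.0 - mi)),
        input_cost=params.input_base * (1.0 + params.input_remote_markup * (1.0 - mi)),
        wage=params.wage_ceiling * mi,
        transaction_cost=params.transaction_max * (1.0 - mi),
    )


def classify_regime(shadow_price: float, market: MarketState) -> Regime:
    """Classify market participation from the shadow price.

    ``shadow < farmgate`` -> MIXED (selling production is profitable);
    ``farmgate <= shadow <= food`` -> SUBSISTENCE_GAP (the autarkic price
    gap: no market transactions, self-provisioning is cheapest);
    ``shadow > food`` -> SELL_AND_BUY (buying food beats producing it).
    Boundary values resolve toward the more subsistence-oriented regime.
    An infinite shadow price (no viable production) falls in SELL_AND_BUY.
    """
    if shadow_price < 0 or math.isnan(shadow_price):
        raise ValueError("shadow_price must be non-negative")
    if shadow_price < market.farmgate_price:
        return Regime.MIXED
    if shadow_price <= market.food_price:
        return Regime.SUBSISTENCE_GAP
    return Regime.SELL_AND_BUY
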