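"""Vegetation regrowth, post-fire fuel succession and carbon accounting.

Between fires, live biomass follows logistic growth toward a per-vegetation
carrying capacity — the simplest dynamic with a carrying capacity and a
tunable recovery time, which are the only properties the vegetation-fire
feedback needs.  Cells burned to zero re-seed from a small recolonization
floor; the dead pool decays exponentially.  Burned cells carry an
early-seral (post-fire) fuel model until enough fire-free years have passed
to revert to their vegetation type's forest fuel model; nonforest grass
never reverts to a forest fuel model.

The carbon ledger tracks live C, dead C, total ecosystem carbon
(TEC = (live + dead) x carbon fraction) and cumulative fire-emitted C, with
the closed-budget identity  dTEC + d(emitted C) = net growth C  holding
exactly every year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CARBON_FRACTION
from .landscape import VEG_FUEL_MODEL, LandscapeState

__all__ = [
    "VegParams",
    "DEFAULT_VEG_PARAMS",
    "CarbonLedger",
    "logistic_biomass",
    "regrow",
    "succeed_fuel_models",
    "update_ledger",
]


@dataclass(frozen=True)
class VegParams:
    """Growth and succession parameters of one vegetation type.

    ``carrying_capacity`` (g/m2) caps live biomass; ``rate`` (per year) is
    the intrinsic logistic growth rate, which sets post-fire recovery time
    and hence how long fuel limitation persists; ``recolonization_floor``
    (g/m2) re-seeds cells burned to zero; ``years_to_forest_fuel`` is the
    fire-free delay before a burned cell's fuel model reverts from post-fire
    to the type's forest fuel model.
    """

    carrying_capacity: float
    rate: float
    recolonization_floor: float = 100.0
    years_to_forest_fuel: int = 15

    def __post_init__(self):
        if self.carrying_capacity <= 0:
            raise ValueError("carrying_capacity must be positive")
        if self.rate <= 0:
            raise ValueError("growth rate must be positive")
        if self.recolonization_floor < 0:
            raise ValueError("recolonization floor must be nonnegative")


DEFAULT_VEG_PARAMS = {
    "oak_woodland": VegParams(6500.0, 0.10, 150.0, 12),
    "mixed_conifer": VegParams(16000.0, 0.09, 150.0, 15),
    "red_fir_subalpine": VegParams(13000.0, 0.07, 100.0, 20),
    "alpine_sparse": VegParams(1800.0, 0.05, 50.0, 25),
    "grass": VegParams(600.0, 1.2, 50.0, 1),
}

#: Exponential decay rate of the dead pool, per year.
DEFAULT_DEAD_DECAY = 0.05


def logistic_biomass(b0, k, r, t):
    """Closed-form logistic trajectory B(t) from B(0)=b0 toward capacity k."""
    b0 = np.asarray(b0, dtype=float)
    e = np.exp(r * t)
    return k * b0 * e / (k + b0 * (e - 1.0))


def regrow(
    landscape: LandscapeState,
    veg_params=None,
    dt: float = 1.0,
    dead_decay: float = DEFAULT_DEAD_DECAY,
) -> LandscapeState:
    """Advance vegetation by ``dt`` years (in place).

    Live biomass follows the closed-form logistic toward the type's carrying
    capacity; cells at zero are first seeded from the recolonization floor.
    The dead pool decays as exp(-dead_decay * dt); time-since-fire advances.
    """
    if dt < 1:
        raise ValueError("dt must be at least one year")
    veg_params = veg_params or DEFAULT_VEG_PARAMS
    for veg_name, vp in veg_params.items():
        mask = landscape.veg_type == veg_name
        if not mask.any():
            continue
        b = landscape.live_biomass[mask]
        if vp.recolonization_floor > 0:
            b = np.where(b <= 0.0, min(vp.recolonization_floor, vp.carrying_capacity), b)
        landscape.live_biomass[mask] = logistic_biomass(
            b, vp.carrying_capacity, vp.rate, dt
        )
    landscape.dead_biomass *= np.exp(-dead_decay * dt)
    landscape.time_since_fire += int(dt)
    landscape.year += int(dt)
    return landscape


def succeed_fuel_models(landscape: LandscapeState, veg_params=None) -> LandscapeState:
    """Revert post-fire fuel models after the configured fire-free delay.

    A burned cell regains its vegetation type's forest fuel model once
    time_since_fire >= years_to_forest_fuel; grass cells go back to the
    grass fuel model (never a forest one).
    """
    veg_params = veg_params or DEFAULT_VEG_PARAMS
    postfire = landscape.fuel_model == "postfire"
    if not postfire.any():
        return landscape
    for veg_name, vp in veg_params.items():
        mask = (
            postfire
            & (landscape.veg_type == veg_name)
            & (landscape.time_since_fire >= vp.years_to_forest_fuel)
        )
        if mask.any():
            landscape.fuel_model[mask] = VEG_FUEL_MODEL.get(veg_name, "grass")
    return landscape


@dataclass
class CarbonLedger:
    """Annual landscape carbon accounts (all kg C)."""

    years: list = field(default_factory=list)
    live_c: list = field(default_factory=list)
    dead_c: list = field(default_factory=list)
    tec: list = field(default_factory=list)
    cum_emitted_c: list = field(default_factory=list)
    net_growth_c: list = field(default_factory=list)

    def to_frame(self, replicate=0, scenario="", mode="", transect="") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "replicate": replicate,
                "scenario": scenario,
                "mode": mode,
                "transect": transect,
                "live_c_kg": self.live_c,
                "dead_c_kg": self.dead_c,
                "tec_kg": self.tec,
                "cum_emitted_c_kg": self.cum_emitted_c,
                "net_growth_c_kg": self.net_growth_c,
            }
        )


def update_ledger(
    ledger: CarbonLedger,
    landscape: LandscapeState,
    events_this_year=(),
    net_growth_c: float = 0.0,
) -> CarbonLedger:
    """Append one year of carbon accounts.

    ``net_growth_c`` is the year's net non-fire change in biomass C (growth
    minus dead-pool decay), supplied by the caller from biomass totals before
    and after the regrowth step so the budget identity
    dTEC + d(cumulative emitted C) = net growth C  is exact.
    """
    gm2_to_kg = 10.0 * landscape.cell_area
    live_c = float(landscape.live_biomass.sum()) * gm2_to_kg * CARBON_FRACTION
    dead_c = float(landscape.dead_biomass.sum()) * gm2_to_kg * CARBON_FRACTION
    emitted = float(sum(e.c_efflux for e in events_this_year))
    prev_cum = ledger.cum_emitted_c[-1] if ledger.cum_emitted_c else 0.0

    ledger.years.append(int(landscape.year))
    ledger.live_c.append(live_c)
    ledger.dead_c.append(dead_c)
    ledger.tec.append(live_c + dead_c)
    ledger.cum_emitted_c.append(prev_cum + emitted)
    ledger.net_growth_c.append(float(net_growth_c))
    return ledger
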