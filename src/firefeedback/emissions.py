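"""Fire emissions via the FINN algorithm.

Emissions of each chemical species are dry biomass burned times a constant
emission factor (g of species per kg of dry biomass).  The factors are means
for western-US wildfires: CO2 1454, CO 89.3, CH4 4.9, submicron aerosols
(PM1) 26 and organic aerosols (OA) 24.3 g/kg.  Dry biomass burned is
recovered from the fire engine's carbon efflux by the inverse of the
engine's carbon fraction (0.5), so the engine-to-emissions round trip is
exact.  Every species total is therefore an exact scalar multiple of the
CO2 total.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from types import MappingProxyType

import numpy as np
import pandas as pd

from .engine import CARBON_FRACTION

__all__ = [
    "EMISSION_FACTORS",
    "dry_biomass_from_c",
    "compute_emissions",
    "aggregate_emissions",
    "round_half_up",
]

#: Western-US wildfire emission factors, g per kg dry biomass burned
#: (immutable during a run).
EMISSION_FACTORS = MappingProxyType(
    {
        "CO2": 1454.0,
        "CO": 89.3,
        "CH4": 4.9,
        "PM1": 26.0,
        "OA": 24.3,
    }
)

KG_PER_TG = 1e9


def dry_biomass_from_c(c_efflux):
    """Dry biomass burned (kg) from fire carbon efflux (kg C)."""
    c = np.asarray(c_efflux, dtype=float)
    if np.any(c < 0):
        raise ValueError("carbon efflux must be nonnegative")
    out = c / CARBON_FRACTION
    return float(out) if np.isscalar(c_efflux) else out


def compute_emissions(dry_biomass, factors=EMISSION_FACTORS):
    """Species emissions (kg) from dry biomass burned (kg).

    emission_s = dry_biomass x factor_s / 1000 — strictly linear in the
    biomass, so ratios between species equal ratios of their factors.
    """
    b = np.asarray(dry_biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("dry biomass must be nonnegative")
    scalar = np.isscalar(dry_biomass)
    return {
        sp: (float(b * f / 1000.0) if scalar else b * f / 1000.0)
        for sp, f in factors.items()
    }


def aggregate_emissions(events: pd.DataFrame, factors=EMISSION_FACTORS) -> pd.DataFrame:
    """Cumulative per-replicate emissions (Tg) with quartiles across
    replicates.

    ``events`` is a fire-event table with at least ``scenario``, ``mode``,
    ``replicate`` and ``c_efflux_kg`` columns (``consumed_kg`` is used
    directly when present).  Returns one row per (scenario, mode, species)
    with the 25th percentile, median and 75th percentile of cumulative
    emissions over the replicate set.  An empty event table yields an empty
    frame.
    """
    out_cols = ["scenario", "mode", "species", "q25_tg", "median_tg", "q75_tg"]
    if events.empty:
        return pd.DataFrame(columns=out_cols)
    df = events.copy()
    if "consumed_kg" in df.columns:
        biomass = df["consumed_kg"].astype(float)
    else:
        biomass = dry_biomass_from_c(df["c_efflux_kg"].astype(float).to_numpy())
    df["_biomass_kg"] = np.asarray(biomass)
    per_rep = (
        df.groupby(["scenario", "mode", "replicate"])["_biomass_kg"].sum().reset_index()
    )
    rows = []
    for (scenario, mode), grp in per_rep.groupby(["scenario", "mode"]):
        biomass_kg = grp["_biomass_kg"].to_numpy()
        for sp, f in factors.items():
            totals_tg = biomass_kg * f / 1000.0 / KG_PER_TG
            q25, med, q75 = np.percentile(totals_tg, [25, 50, 75])
            rows.append(
                {
                    "scenario": scenario,
                    "mode": mode,
                    "species": sp,
                    "q25_tg": q25,
                    "median_tg": med,
                    "q75_tg": q75,
                }
            )
    return pd.DataFrame(rows, columns=out_cols)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up rounding used for reported emission tables (13.572 -> 13.6)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
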