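"""Stochastic fire engine: ignition, weather, spread and fire effects.

Each simulation year, random ignitions land uniformly on the raster; a draw
from the fire-probability distribution (per-fuel-model base probability
scaled by a fire-weather multiplier) decides whether an ignition becomes a
fire; a draw from the fire-size model sets the fire's maximum (target) size;
and the fire then grows cell by cell from the ignition, always annexing the
frontier neighbor with the highest spread score, until it reaches the target
or runs out of burnable fuel.  Fuel limitation — fires truncated by cells
whose biomass has not recovered from earlier burns — is what makes fire
self-limiting in this model.

Severity (fraction of live biomass killed) increases with fuel load and the
fire-weather percentile; killed-but-unconsumed biomass moves to the dead
pool, so every fire satisfies an exact dry-mass balance:
pre(live + dead) = post(live + dead) + consumed.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import ClimateSeries, LandscapeState

__all__ = [
    "FuelModel",
    "FireEvent",
    "SeverityParams",
    "DEFAULT_FUEL_MODELS",
    "CARBON_FRACTION",
    "draw_ignitions",
    "ignition_becomes_fire",
    "draw_weather",
    "weather_multiplier",
    "spread_fire",
    "apply_fire",
    "is_burnable",
    "events_to_frame",
    "fuel_models_to_frame",
    "fuel_models_from_frame",
]

#: Carbon fraction of dry biomass; its inverse is used by the emissions module.
CARBON_FRACTION = 0.5

#: Live + dead biomass (g/m2) below which a cell cannot carry fire.
DEFAULT_BURN_THRESHOLD = 200.0


@dataclass(frozen=True)
class FuelModel:
    """Fuels of one vegetation state.

    ``ros`` is a dimensionless relative rate of spread (grass highest among
    the defaults); ``burn_threshold`` is the live+dead biomass (g/m2) below
    which the cell is not burnable; the consumption fractions give the share
    of killed live biomass and of the dead pool consumed by a fire;
    ``base_fire_prob`` is the per-ignition probability that an ignition in
    this fuel becomes a fire under median fire weather.
    """

    id: str
    ros: float
    burn_threshold: float = DEFAULT_BURN_THRESHOLD
    live_consumption: float = 0.3
    dead_consumption: float = 0.8
    base_fire_prob: float = 0.2

    def __post_init__(self):
        if self.ros < 0:
            raise ValueError("rate of spread must be nonnegative")


#: Default fuel models.  The grass model has the highest rate of spread;
#: the post-fire (early-seral) model is grass-like but slower.
DEFAULT_FUEL_MODELS = {
    fm.id: fm
    for fm in (
        FuelModel("grass", ros=3.0, base_fire_prob=0.40, live_consumption=0.8),
        FuelModel("oak_woodland", ros=1.2, base_fire_prob=0.25),
        FuelModel("mixed_conifer", ros=1.0, base_fire_prob=0.20),
        FuelModel("red_fir", ros=0.8, base_fire_prob=0.12),
        FuelModel("sparse", ros=0.3, base_fire_prob=0.05),
        FuelModel("postfire", ros=2.0, base_fire_prob=0.30, live_consumption=0.6),
    )
}


@dataclass
class SeverityParams:
    """Coefficients of the severity response.

    severity = clip(s0 + s1 * weather + s2 * (live+dead)/reference_load, 0, 1);
    severity rises with the fire-weather percentile and with fuel load.
    """

    s0: float = 0.2
    s1: float = 0.5
    s2: float = 0.25
    reference_load: float = 15000.0  # g/m2


@dataclass
class FireEvent:
    """One simulated fire and its effects."""

    year: int
    ignition: tuple[int, int]
    target_size: float                     # ha, the drawn maximum size
    realized_size: float = 0.0             # ha, |burned_cells| * cell_area
    burned_cells: list = field(default_factory=list)
    severity: np.ndarray | None = None     # aligned with burned_cells
    consumed_dry_biomass: float = 0.0      # kg
    c_efflux: float = 0.0                  # kg C
    weather: float = 0.0                   # fire-weather percentile

    @property
    def mean_severity(self) -> float:
        if self.severity is None or len(self.severity) == 0:
            return 0.0
        return float(np.mean(self.severity))


class UnknownFuelModelError(KeyError):
    pass


def _fuel_for(landscape: LandscapeState, row: int, col: int, fuel_models) -> FuelModel:
    fid = str(landscape.fuel_model[row, col])
    try:
        return fuel_models[fid]
    except KeyError:
        raise UnknownFuelModelError(f"cell ({row}, {col}) has unknown fuel model {fid!r}")


def is_burnable(landscape: LandscapeState, row: int, col: int, fuel_models) -> bool:
    """A cell is burnable when its live+dead load meets its fuel model's
    burnable threshold."""
    fm = _fuel_for(landscape, row, col, fuel_models)
    load = landscape.live_biomass[row, col] + landscape.dead_biomass[row, col]
    return bool(load >= fm.burn_threshold)


def draw_ignitions(landscape: LandscapeState, rate: float, rng) -> list[tuple[int, int]]:
    """Poisson(rate) random ignition locations, uniform over the grid,
    without repetition within the year."""
    if rate < 0:
        raise ValueError("ignition rate must be nonnegative")
    n = int(rng.poisson(rate))
    if n == 0:
        return []
    n = min(n, landscape.n_cells)
    flat = rng.choice(landscape.n_cells, size=n, replace=False)
    n_cols = landscape.shape[1]
    return [(int(f) // n_cols, int(f) % n_cols) for f in flat]


def weather_multiplier(weather: float, gain: float = 2.0) -> float:
    """Fire-probability multiplier of the weather percentile.

    Linear in the percentile with unit mean under uniform weather
    (multiplier = gain * weather, gain defaulting to 2).
    """
    return gain * weather


def ignition_becomes_fire(
    cell: tuple[int, int],
    landscape: LandscapeState,
    fuel_models,
    weather: float,
    rng,
    weather_gain: float = 2.0,
) -> bool:
    """Bernoulli draw deciding whether an ignition becomes a fire.

    Probability = clip(base_fire_prob(fuel model) * weather multiplier, 0, 1);
    cells below their burnable-biomass threshold never ignite.  One uniform
    is consumed from ``rng`` on every call so paired simulations sharing the
    stream stay aligned.
    """
    row, col = cell
    fm = _fuel_for(landscape, row, col, fuel_models)
    u = float(rng.uniform())
    if not is_burnable(landscape, row, col, fuel_models):
        return False
    p = float(np.clip(fm.base_fire_prob * weather_multiplier(weather, weather_gain), 0.0, 1.0))
    return u < p


def draw_weather(climate: ClimateSeries, rng) -> float:
    """One fire-weather percentile draw from the scenario's configured
    distribution (shared between the static and dynamic runs of a pair)."""
    dist = climate.weather_dist
    kind = dist.get("kind", "uniform")
    if kind == "degenerate":
        return float(dist.get("value", 0.5))
    if kind == "uniform":
        return float(rng.uniform(dist.get("low", 0.0), dist.get("high", 1.0)))
    if kind == "beta":
        return float(rng.beta(dist.get("a", 2.0), dist.get("b", 2.0)))
    raise ValueError(f"unknown weather distribution kind {kind!r}")


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def spread_fire(
    landscape: LandscapeState,
    ignition: tuple[int, int],
    target_size: float,
    weather: float,
    fuel_models,
    weather_gain: float = 2.0,
) -> FireEvent:
    """Grow a fire from the ignition to at most the drawn target size.

    The burned set grows by repeatedly annexing the frontier cell with the
    highest spread score — fuel rate-of-spread x weather multiplier divided
    by the Euclidean distance from the ignition — skipping cells below their
    burnable threshold.  Growth stops when the target size is reached or no
    burnable frontier remains (fuel limitation), so realized size never
    exceeds the target.  Ties in score break deterministically by (row, col).
    """
    year = landscape.year
    event = FireEvent(year=year, ignition=tuple(ignition), target_size=float(target_size), weather=float(weather))
    r0, c0 = ignition
    if not is_burnable(landscape, r0, c0, fuel_models):
        return event

    n_rows, n_cols = landscape.shape
    n_target = max(1, int(math.floor(target_size / landscape.cell_area + 1e-9)))
    wmult = weather_multiplier(weather, weather_gain)

    burned: list[tuple[int, int]] = []
    in_set = np.zeros(landscape.shape, dtype=bool)
    queued = np.zeros(landscape.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []

    def push_neighbors(r, c):
        for dr, dc in _NEIGHBORS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                continue
            if in_set[rr, cc] or queued[rr, cc]:
                continue
            if not is_burnable(landscape, rr, cc, fuel_models):
                continue
            fm = _fuel_for(landscape, rr, cc, fuel_models)
            dist = math.hypot(rr - r0, cc - c0)
            score = fm.ros * wmult / max(dist, 1e-12)
            heapq.heappush(heap, (-score, rr, cc))
            queued[rr, cc] = True

    burned.append((r0, c0))
    in_set[r0, c0] = True
    push_neighbors(r0, c0)
    while len(burned) < n_target and heap:
        _, r, c = heapq.heappop(heap)
        if in_set[r, c]:
            continue
        burned.append((r, c))
        in_set[r, c] = True
        push_neighbors(r, c)

    event.burned_cells = burned
    event.realized_size = len(burned) * landscape.cell_area
    return event


def apply_fire(
    landscape: LandscapeState,
    event: FireEvent,
    fuel_models,
    severity_params: SeverityParams | None = None,
) -> tuple[LandscapeState, FireEvent]:
    """Apply a fire's effects to the landscape and fill in the event totals.

    Per burned cell: severity (an increasing function of fuel load and the
    fire-weather percentile, clipped to [0, 1]) kills that fraction of live
    biomass; the fuel model's live consumption fraction of the killed biomass
    and dead consumption fraction of the dead pool are consumed; killed but
    unconsumed live biomass transfers to the dead pool; the fuel model
    switches to the post-fire model and time-since-fire resets to 0.
    Dry-mass balance (pre live+dead = post live+dead + consumed) is exact.
    """
    sp = severity_params or SeverityParams()
    if not event.burned_cells:
        event.severity = np.zeros(0)
        return landscape, event

    consumed_gm2_total = 0.0
    severities = np.empty(len(event.burned_cells))
    for k, (r, c) in enumerate(event.burned_cells):
        fm = _fuel_for(landscape, r, c, fuel_models)
        live = float(landscape.live_biomass[r, c])
        dead = float(landscape.dead_biomass[r, c])
        load = live + dead
        sev = float(np.clip(sp.s0 + sp.s1 * event.weather + sp.s2 * load / sp.reference_load, 0.0, 1.0))
        severities[k] = sev

        killed = sev * live
        consumed_live = fm.live_consumption * killed
        consumed_dead = fm.dead_consumption * dead
        landscape.live_biomass[r, c] = live - killed
        landscape.dead_biomass[r, c] = dead + (killed - consumed_live) - consumed_dead
        consumed_gm2_total += consumed_live + consumed_dead

        landscape.fuel_model[r, c] = "postfire"
        landscape.time_since_fire[r, c] = 0

    event.severity = severities
    # 1 g/m2 over 1 ha = 10 kg
    event.consumed_dry_biomass = consumed_gm2_total * 10.0 * landscape.cell_area
    event.c_efflux = CARBON_FRACTION * event.consumed_dry_biomass
    return landscape, event


# ---------------------------------------------------------------------------
# tabular I/O

_EVENT_COLS = [
    "year",
    "replicate",
    "scenario",
    "mode",
    "transect",
    "ignition_row",
    "ignition_col",
    "target_ha",
    "realized_ha",
    "consumed_kg",
    "c_efflux_kg",
    "mean_severity",
]


def events_to_frame(events, replicate=0, scenario="", mode="", transect="") -> pd.DataFrame:
    """Flatten FireEvents into the standard fire-event table."""
    rows = [
        {
            "year": e.year,
            "replicate": replicate,
            "scenario": scenario,
            "mode": mode,
            "transect": transect,
            "ignition_row": e.ignition[0],
            "ignition_col": e.ignition[1],
            "target_ha": e.target_size,
            "realized_ha": e.realized_size,
            "consumed_kg": e.consumed_dry_biomass,
            "c_efflux_kg": e.c_efflux,
            "mean_severity": e.mean_severity,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLS)


def fuel_models_to_frame(fuel_models) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": fm.id,
                "ros": fm.ros,
                "burn_threshold": fm.burn_threshold,
                "live_consumption": fm.live_consumption,
                "dead_consumption": fm.dead_consumption,
                "base_fire_prob": fm.base_fire_prob,
            }
            for fm in fuel_models.values()
        ]
    )


def fuel_models_from_frame(df: pd.DataFrame) -> dict:
    return {
        str(t.id): FuelModel(
            id=str(t.id),
            ros=float(t.ros),
            burn_threshold=float(t.burn_threshold),
            live_consumption=float(t.live_consumption),
            dead_consumption=float(t.dead_consumption),
            base_fire_prob=float(t.base_fire_prob),
        )
        for t in df.itertuples(index=False)
    }
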