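"""Synthetic transect landscapes and climate-deficit series.

The simulator needs three ingredients that real applications would read from
GIS layers and downscaled climate projections: an elevation-zoned vegetation
raster with initial aboveground biomass, and a per-scenario annual series of
cumulative monthly moisture deficit.  This module generates seeded stand-ins
with the structure the downstream analysis assumes — an elevation gradient
spanning a prescribed range, vegetation bands keyed to elevation, nonforest
grass patches concentrated at low elevation, and a warming-driven upward
deficit trend — so the whole pipeline is testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VEG_TYPES",
    "TransectSpec",
    "ClimateSeries",
    "LandscapeState",
    "generate_transect",
    "generate_climate",
    "default_transect_specs",
    "write_matrix",
    "read_matrix",
    "write_tiff",
    "read_tiff",
]

#: Vegetation types, low to high elevation, plus nonforest grass.
VEG_TYPES = (
    "oak_woodland",
    "mixed_conifer",
    "red_fir_subalpine",
    "alpine_sparse",
    "grass",
)

#: Default initial aboveground biomass means, g/m2 dry matter.
DEFAULT_BIOMASS_MEAN = {
    "oak_woodland": 6000.0,
    "mixed_conifer": 15000.0,
    "red_fir_subalpine": 12000.0,
    "alpine_sparse": 1500.0,
    "grass": 500.0,
}

#: Elevation-band fractions of each transect's range for the forest types.
DEFAULT_BAND_FRACTIONS = (
    ("oak_woodland", (0.0, 0.30)),
    ("mixed_conifer", (0.30, 0.60)),
    ("red_fir_subalpine", (0.60, 0.85)),
    ("alpine_sparse", (0.85, 1.0)),
)

#: The three mountain transects: name -> (min elevation m, max elevation m).
DEFAULT_ELEVATION_RANGES = {
    "south": (290.0, 4388.0),
    "central": (252.0, 3978.0),
    "north": (275.0, 2591.0),
}

#: Forest fuel model per vegetation type; grass keeps the grass fuel model.
VEG_FUEL_MODEL = {
    "oak_woodland": "oak_woodland",
    "mixed_conifer": "mixed_conifer",
    "red_fir_subalpine": "red_fir",
    "alpine_sparse": "sparse",
    "grass": "grass",
}


class ConfigurationError(ValueError):
    """Raised for inconsistent generator specifications."""


@dataclass(frozen=True)
class TransectSpec:
    """Specification of one synthetic mountain transect.

    Parameters
    ----------
    name
        Transect label (``north``, ``central`` or ``south``).
    n_rows, n_cols
        Grid dimensions; row 0 is the north edge.
    cell_area
        Cell area in hectares.
    elevation_range
        (min, max) elevation in metres; the generated field spans this
        range exactly.
    veg_zonation
        Ordered ``(vegetation_type, (lo_m, hi_m))`` bands that partition
        the elevation range without overlap.
    initial_biomass_mean
        g/m2 dry biomass mean per vegetation type.
    biomass_cv
        Coefficient of variation of the seeded lognormal biomass noise
        (0 gives exactly the type mean everywhere).
    grass_fraction
        Fraction of cells converted to nonforest grass patches, biased
        toward low elevation.
    elevation_noise
        Amplitude of the seeded 2-D noise added to the column-wise
        gradient, as a fraction of the elevation range.
    seed
        Generator seed; the raster is a pure function of (spec, seed).
    """

    name: str = "north"
    n_rows: int = 100
    n_cols: int = 100
    cell_area: float = 1.0
    elevation_range: tuple[float, float] = DEFAULT_ELEVATION_RANGES["north"]
    veg_zonation: tuple = ()  # filled from DEFAULT_BAND_FRACTIONS if empty
    initial_biomass_mean: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOMASS_MEAN)
    )
    biomass_cv: float = 0.15
    grass_fraction: float = 0.10
    elevation_noise: float = 0.05
    seed: int = 0

    def resolved_zonation(self) -> tuple:
        lo, hi = self.elevation_range
        if self.veg_zonation:
            return tuple(self.veg_zonation)
        span = hi - lo
        return tuple(
            (veg, (lo + f0 * span, lo + f1 * span))
            for veg, (f0, f1) in DEFAULT_BAND_FRACTIONS
        )

    def validate(self) -> None:
        lo, hi = self.elevation_range
        if not (lo < hi):
            raise ConfigurationError(f"elevation_range min must be < max, got {self.elevation_range}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigurationError("grid must be non-empty")
        if self.cell_area <= 0:
            raise ConfigurationError("cell_area must be positive")
        bands = self.resolved_zonation()
        prev_hi = lo
        for veg, (b_lo, b_hi) in bands:
            if veg not in VEG_TYPES:
                raise ConfigurationError(f"unknown vegetation type {veg!r}")
            if not np.isclose(b_lo, prev_hi):
                raise ConfigurationError(
                    f"vegetation bands must partition [{lo}, {hi}] without gaps or "
                    f"overlap; band {veg!r} starts at {b_lo}, expected {prev_hi}"
                )
            if b_hi <= b_lo:
                raise ConfigurationError(f"band {veg!r} has nonpositive width")
            prev_hi = b_hi
        if not np.isclose(prev_hi, hi):
            raise ConfigurationError(
                f"vegetation bands cover [{lo}, {prev_hi}] but the elevation range "
                f"extends to {hi}"
            )


@dataclass
class ClimateSeries:
    """Annual cumulative moisture-deficit series for one climate scenario.

    ``deficit[i]`` is the cumulative monthly moisture deficit (mm) for year
    ``years[i]``; ``weather_dist`` parameterizes the fire-weather percentile
    draw and is shared between the static and dynamic members of a paired
    experiment.
    """

    scenario: str
    years: np.ndarray
    deficit: np.ndarray
    weather_dist: dict = field(default_factory=lambda: {"kind": "uniform"})

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.deficit = np.asarray(self.deficit, dtype=float)
        if self.years.shape != self.deficit.shape:
            raise ConfigurationError("years and deficit must be the same length")
        if np.any(self.deficit < 0):
            raise ConfigurationError("deficit must be nonnegative")

    def deficit_for(self, year: int) -> float:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= len(self.years):
            raise KeyError(f"year {year} outside climate series")
        return float(self.deficit[idx])


@dataclass
class LandscapeState:
    """Raster state shared by the fire engine and vegetation dynamics.

    All per-cell fields are (n_rows, n_cols) arrays; biomass pools are g/m2
    dry matter.  ``fuel_model`` holds fuel-model ids as strings; nonforest
    grass cells carry the grass fuel model.
    """

    veg_type: np.ndarray       # unicode codes from VEG_TYPES
    elevation: np.ndarray      # m
    live_biomass: np.ndarray   # g/m2
    dead_biomass: np.ndarray   # g/m2
    fuel_model: np.ndarray     # fuel model ids
    time_since_fire: np.ndarray  # years
    year: int
    cell_area: float           # ha

    @property
    def shape(self) -> tuple[int, int]:
        return self.veg_type.shape

    @property
    def n_cells(self) -> int:
        return int(self.veg_type.size)

    def total_biomass(self) -> float:
        """Landscape total dry biomass in kg (live + dead)."""
        gm2 = float(self.live_biomass.sum() + self.dead_biomass.sum())
        # 1 g/m2 over 1 ha = 10 kg
        return gm2 * 10.0 * self.cell_area

    def copy(self) -> "LandscapeState":
        return LandscapeState(
            veg_type=self.veg_type.copy(),
            elevation=self.elevation.copy(),
            live_biomass=self.live_biomass.copy(),
            dead_biomass=self.dead_biomass.copy(),
            fuel_model=self.fuel_model.copy(),
            time_since_fire=self.time_since_fire.copy(),
            year=self.year,
            cell_area=self.cell_area,
        )


def generate_transect(spec: TransectSpec) -> LandscapeState:
    """Generate a seeded synthetic transect landscape.

    The elevation field is a west-east column gradient plus low-amplitude
    seeded 2-D noise, rescaled to span ``spec.elevation_range`` exactly;
    vegetation follows the zonation bands deterministically, after which a
    seeded fraction of cells (biased toward low elevation) becomes nonforest
    grass.  Initial live biomass is lognormal around the type mean; the dead
    pool starts at 10% of live.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.elevation_range

    cols = np.linspace(0.0, 1.0, spec.n_cols)
    base = np.tile(cols, (spec.n_rows, 1))
    if spec.elevation_noise > 0:
        noise = rng.normal(0.0, spec.elevation_noise, size=(spec.n_rows, spec.n_cols))
        base = base + noise
    # rescale so min/max hit the printed range exactly
    bmin, bmax = base.min(), base.max()
    if bmax > bmin:
        base = (base - bmin) / (bmax - bmin)
    else:
        base = np.zeros_like(base)
    elevation = lo + base * (hi - lo)

    bands = spec.resolved_zonation()
    veg = np.empty(elevation.shape, dtype="U20")
    for veg_name, (b_lo, b_hi) in bands:
        mask = (elevation >= b_lo) & (elevation <= b_hi) if (b_hi == hi) else (
            (elevation >= b_lo) & (elevation < b_hi)
        )
        veg[mask] = veg_name
    if np.any(veg == ""):
        raise ConfigurationError("vegetation bands do not cover the elevation range")

    if spec.grass_fraction > 0:
        # weight grass conversion toward low elevation
        w = (hi - elevation).ravel()
        w = w / w.sum()
        n_grass = int(round(spec.grass_fraction * veg.size))
        idx = rng.choice(veg.size, size=n_grass, replace=False, p=w)
        veg.ravel()[idx] = "grass"

    live = np.empty(elevation.shape, dtype=float)
    for veg_name in VEG_TYPES:
        mask = veg == veg_name
        if not mask.any():
            continue
        mean = float(spec.initial_biomass_mean.get(veg_name, 0.0))
        if spec.biomass_cv > 0 and mean > 0:
            sdlog = np.sqrt(np.log1p(spec.biomass_cv**2))
            mulog = np.log(mean) - 0.5 * sdlog**2
            live[mask] = rng.lognormal(mulog, sdlog, size=int(mask.sum()))
        else:
            live[mask] = mean
    dead = 0.1 * live

    fuel = np.empty(elevation.shape, dtype="U20")
    for veg_name, fm in VEG_FUEL_MODEL.items():
        fuel[veg == veg_name] = fm

    return LandscapeState(
        veg_type=veg,
        elevation=elevation,
        live_biomass=live,
        dead_biomass=dead,
        fuel_model=fuel,
        time_since_fire=np.full(elevation.shape, 100, dtype=int),
        year=2010,
        cell_area=spec.cell_area,
    )


def generate_climate(
    scenario: str,
    trend: float,
    noise_sd: float,
    seed: int,
    base: float = 150.0,
    start_year: int = 2010,
    end_year: int = 2099,
    weather_dist: dict | None = None,
) -> ClimateSeries:
    """Generate an annual moisture-deficit series with a linear warming trend.

    ``trend`` is mm per decade; ``noise_sd`` is the standard deviation of the
    seeded Gaussian interannual noise.  Values are truncated at 0.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be nonnegative")
    years = np.arange(start_year, end_year + 1)
    t = years - start_year
    rng = np.random.default_rng(seed)
    deficit = base + (trend / 10.0) * t
    if noise_sd > 0:
        deficit = deficit + rng.normal(0.0, noise_sd, size=len(years))
    deficit = np.clip(deficit, 0.0, None)
    return ClimateSeries(
        scenario=scenario,
        years=years,
        deficit=deficit,
        weather_dist=dict(weather_dist) if weather_dist else {"kind": "uniform"},
    )


def default_transect_specs(
    n_rows: int = 100, n_cols: int = 100, seed: int = 0
) -> list[TransectSpec]:
    """The three default transects with the printed elevation ranges.

    The north transect gets a larger grass fraction: it is the least
    topographically diverse of the three, with more of its area in
    low-elevation vegetation that is available to burn for a larger part of
    the year.
    """
    specs = []
    grass_fraction = {"south": 0.08, "central": 0.10, "north": 0.18}
    for i, name in enumerate(("south", "central", "north")):
        specs.append(
            TransectSpec(
                name=name,
                n_rows=n_rows,
                n_cols=n_cols,
                elevation_range=DEFAULT_ELEVATION_RANGES[name],
                grass_fraction=grass_fraction[name],
                seed=seed + i,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# raster I/O: plain-text matrices (primary) and single-band TIFF


def write_matrix(path, array: np.ndarray) -> None:
    """Write a single-band raster as a plain whitespace-separated matrix."""
    np.savetxt(path, np.asarray(array), fmt="%.8g")


def read_matrix(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def write_tiff(path, array: np.ndarray) -> None:
    """Write a single-band float32 TIFF layer."""
    import tifffile

    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)
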