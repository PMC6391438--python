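"""Paired static/dynamic simulation experiments.

The core computational experiment pairs two otherwise-identical simulations
on every (transect, scenario, replicate) cell:

* **static** — the large-fire size distribution stays the baseline fit,
  conditioned on projected climate and the *initial* (historic) biomass;
* **dynamic** — every ten years the fire-size model is re-estimated with the
  biomass covariate taken from the fire-impacted landscape of the decade
  just finished, and size draws condition on that decadal biomass snapshot.

Static and dynamic members of a pair share the same named random substreams
(ignition, weather, fire-probability, fire-size, small-fire), so toggling
the mode changes nothing until the first re-estimation decade; after that,
fire sizes diverge only through the re-fitted model and its biomass input.
This is the mechanism by which everything except the vegetation-fire
feedback is held constant between the two scenarios.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import engine, firesize, vegetation
from .landscape import (
    ClimateSeries,
    LandscapeState,
    TransectSpec,
    default_transect_specs,
    generate_climate,
    generate_transect,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "TransectBaseline",
    "build_baseline",
    "run_replicate",
    "run_experiment",
]

# named random substreams; static/dynamic pairs share all of them
_STREAMS = {"ignition": 0, "weather": 1, "fire_prob": 2, "fire_size": 3, "small_fire": 4}


@dataclass
class ExperimentConfig:
    """Full configuration of a paired static/dynamic experiment.

    Every default printed here is a config key; :meth:`from_yaml` /
    :meth:`to_yaml` round-trip the structured key-value file.
    """

    # simulation span and design
    start_year: int = 2010
    end_year: int = 2099
    n_replicates: int = 10
    reestimation_interval: int = 10
    master_seed: int = 0
    modes: tuple[str, ...] = ("static", "dynamic")

    # landscape
    transect_names: tuple[str, ...] = ("south", "central", "north")
    n_rows: int = 100
    n_cols: int = 100

    # climate scenarios: three variants standing in for three climate models
    scenarios: dict = field(
        default_factory=lambda: {
            "climA": {"trend": 20.0, "noise_sd": 25.0, "base": 150.0},
            "climB": {"trend": 30.0, "noise_sd": 25.0, "base": 160.0},
            "climC": {"trend": 15.0, "noise_sd": 25.0, "base": 140.0},
        }
    )
    weather_dist: dict = field(default_factory=lambda: {"kind": "uniform"})
    weather_gain: float = 2.0

    # ignition and fire-size draws
    ignition_rate: float = 6.0          # expected ignitions per year
    p_large: float = 0.2               # chance an igniting fire is a large fire
    threshold_u: float = 200.0          # ha, large-fire threshold
    small_fire_meanlog: float = 2.5     # lognormal of sub-threshold sizes
    small_fire_sdlog: float = 1.0

    # baseline (historic) large-fire catalogue and its generating parameters
    n_baseline_records: int = 300
    baseline_deficit_mean: float = 150.0
    baseline_deficit_sd: float = 40.0
    true_shape_xi: float = 0.15
    true_a0: float = -1.7
    true_a1: float = 0.002              # per mm deficit
    true_a2: float = 7.0e-5             # per g/m2 biomass
    fix_a2: float | None = None         # set 0.0 to disable the biomass covariate

    # fire effects
    severity: engine.SeverityParams = field(default_factory=engine.SeverityParams)

    # vegetation
    growth_rate_multiplier: float = 1.0
    dead_decay: float = vegetation.DEFAULT_DEAD_DECAY

    def __post_init__(self):
        span = self.end_year - self.start_year + 1
        if span <= 0:
            raise ValueError("end_year must be >= start_year")
        if span % self.reestimation_interval != 0:
            raise ValueError(
                f"reestimation_interval ({self.reestimation_interval}) must divide "
                f"the simulation span ({span} years)"
            )
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for m in self.modes:
            if m not in ("static", "dynamic"):
                raise ValueError(f"unknown mode {m!r}")

    # -- derived pieces -----------------------------------------------------

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    def veg_params(self) -> dict:
        if self.growth_rate_multiplier == 1.0:
            return dict(vegetation.DEFAULT_VEG_PARAMS)
        return {
            name: vegetation.VegParams(
                vp.carrying_capacity,
                vp.rate * self.growth_rate_multiplier,
                vp.recolonization_floor,
                vp.years_to_forest_fuel,
            )
            for name, vp in vegetation.DEFAULT_VEG_PARAMS.items()
        }

    def transect_specs(self) -> list[TransectSpec]:
        specs = default_transect_specs(self.n_rows, self.n_cols, seed=self.master_seed)
        by_name = {s.name: s for s in specs}
        return [by_name[n] for n in self.transect_names]

    def climate_series(self) -> dict[str, ClimateSeries]:
        out = {}
        for i, (name, sc) in enumerate(sorted(self.scenarios.items())):
            out[name] = generate_climate(
                name,
                trend=float(sc["trend"]),
                noise_sd=float(sc["noise_sd"]),
                seed=self.master_seed * 1000 + 77 + i,
                base=float(sc.get("base", 150.0)),
                start_year=self.start_year,
                end_year=self.end_year,
                weather_dist=self.weather_dist,
            )
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modes"] = list(self.modes)
        d["transect_names"] = list(self.transect_names)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "severity" in d and isinstance(d["severity"], dict):
            d["severity"] = engine.SeverityParams(**d["severity"])
        for key in ("modes", "transect_names"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        return cls.from_dict(payload)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


@dataclass
class TransectBaseline:
    """Per-transect inputs shared by every replicate and both modes."""

    spec: TransectSpec
    landscape0: LandscapeState
    records: list
    model: firesize.FireSizeModel


def build_baseline(config: ExperimentConfig, spec: TransectSpec) -> TransectBaseline:
    """Generate the transect landscape, its synthetic historic large-fire
    catalogue, and the baseline GPD fit.

    Record biomass covariates are 3x3 neighborhood means of the initial
    live-biomass raster at each record's ignition cell — the same summary
    dynamic re-estimation recomputes on the fire-impacted raster — so an
    unburned landscape re-fits to exactly the baseline parameters.
    """
    landscape0 = generate_transect(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.master_seed, spawn_key=(999, spec.seed))
    )
    records = []
    years = np.arange(1984, 2015)
    for _ in range(config.n_baseline_records):
        row = int(rng.integers(spec.n_rows))
        col = int(rng.integers(spec.n_cols))
        b = firesize.neighborhood_biomass(landscape0.live_biomass, row, col)
        d = max(0.0, float(rng.normal(config.baseline_deficit_mean, config.baseline_deficit_sd)))
        sigma = float(
            np.exp(config.true_a0 + config.true_a1 * d + config.true_a2 * b)
        )
        size = firesize._conditional_gpd_draw(
            config.threshold_u, config.true_shape_xi, sigma, rng.uniform()
        )
        records.append(
            firesize.FireRecord(
                year=int(rng.choice(years)),
                size_ha=size,
                deficit_mm=d,
                biomass_gm2=b,
                row=row,
                col=col,
            )
        )
    model = firesize.fit(
        records,
        threshold_u=config.threshold_u,
        fix_a2=config.fix_a2,
        fitted_on=f"{spec.name}:baseline",
    )
    return TransectBaseline(spec=spec, landscape0=landscape0, records=records, model=model)


@dataclass
class ExperimentResult:
    """Assembled outputs of a full paired experiment."""

    events: pd.DataFrame      # one row per fire
    ledgers: pd.DataFrame     # one row per (run, year)
    manifest: dict

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(outdir / "fire_events.csv", index=False)
        self.ledgers.to_csv(outdir / "carbon_ledger.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)

    @classmethod
    def load(cls, outdir) -> "ExperimentResult":
        from pathlib import Path

        outdir = Path(outdir)
        with open(outdir / "manifest.json") as fh:
            manifest = json.load(fh)
        return cls(
            events=pd.read_csv(outdir / "fire_events.csv"),
            ledgers=pd.read_csv(outdir / "carbon_ledger.csv"),
            manifest=manifest,
        )


def _stream(config, t_idx, s_idx, replicate, name):
    """Named per-replicate substream, shared between the two modes."""
    ss = np.random.SeedSequence(
        entropy=config.master_seed,
        spawn_key=(t_idx, s_idx, replicate, _STREAMS[name]),
    )
    return np.random.default_rng(ss)


def run_replicate(
    config: ExperimentConfig,
    baseline: TransectBaseline,
    climate: ClimateSeries,
    replicate_id: int,
    mode: str,
    t_idx: int = 0,
    s_idx: int = 0,
    fuel_models=None,
):
    """Run one 90-year simulation for one (transect, scenario, replicate,
    mode) cell.

    Returns ``(events, ledger, landscape)`` where ``events`` is the list of
    applied :class:`~firefeedback.engine.FireEvent` objects.
    """
    if mode not in ("static", "dynamic"):
        raise ValueError(f"mode must be 'static' or 'dynamic', got {mode!r}")
    fuel_models = fuel_models or engine.DEFAULT_FUEL_MODELS
    veg_params = config.veg_params()

    rngs = {name: _stream(config, t_idx, s_idx, replicate_id, name) for name in _STREAMS}

    landscape = baseline.landscape0.copy()
    landscape.year = config.start_year
    covariate_biomass = baseline.landscape0.live_biomass.copy()
    model = baseline.model

    ledger = vegetation.CarbonLedger()
    all_events: list[engine.FireEvent] = []

    for year in range(config.start_year, config.end_year + 1):
        landscape.year = year
        deficit = climate.deficit_for(year)
        year_events: list[engine.FireEvent] = []

        for cell in engine.draw_ignitions(landscape, config.ignition_rate, rngs["ignition"]):
            weather = engine.draw_weather(climate, rngs["weather"])
            if not engine.ignition_becomes_fire(
                cell, landscape, fuel_models, weather, rngs["fire_prob"], config.weather_gain
            ):
                continue
            if rngs["fire_size"].uniform() < config.p_large:
                b_cov = firesize.neighborhood_biomass(covariate_biomass, cell[0], cell[1])
                target = firesize.sample_size(model, deficit, b_cov, rngs["fire_size"])
            else:
                target = firesize.sample_small_size(
                    rngs["small_fire"],
                    config.small_fire_meanlog,
                    config.small_fire_sdlog,
                    min_ha=landscape.cell_area,
                    max_ha=config.threshold_u,
                )
            event = engine.spread_fire(
                landscape, cell, target, weather, fuel_models, config.weather_gain
            )
            if event.realized_size <= 0:
                continue
            landscape, event = engine.apply_fire(
                landscape, event, fuel_models, config.severity
            )
            year_events.append(event)

        biomass_before = landscape.total_biomass()
        vegetation.regrow(landscape, veg_params, 1.0, config.dead_decay)
        vegetation.succeed_fuel_models(landscape, veg_params)
        net_growth_c = (landscape.total_biomass() - biomass_before) * engine.CARBON_FRACTION
        vegetation.update_ledger(ledger, landscape, year_events, net_growth_c)
        all_events.extend(year_events)

        years_done = year - config.start_year + 1
        at_boundary = years_done % config.reestimation_interval == 0
        if at_boundary and year < config.end_year:
            model = firesize.reestimate(model, landscape, climate, baseline.records, mode)
            if mode == "dynamic":
                covariate_biomass = landscape.live_biomass.copy()

    return all_events, ledger, landscape


def run_experiment(config: ExperimentConfig, progress=None) -> ExperimentResult:
    """Run the full factorial: transects x scenarios x replicates x modes.

    Static and dynamic members of each (transect, scenario, replicate) pair
    share identical ignition and weather streams.  A failed replicate aborts
    the experiment with the offending design cell and master seed in the
    message.
    """
    specs = config.transect_specs()
    climates = config.climate_series()
    baselines = [build_baseline(config, spec) for spec in specs]

    event_frames = []
    ledger_frames = []
    for t_idx, baseline in enumerate(baselines):
        tname = baseline.spec.name
        for s_idx, (sname, climate) in enumerate(sorted(climates.items())):
            for rep in range(config.n_replicates):
                for mode in config.modes:
                    try:
                        events, ledger, _ = run_replicate(
                            config, baseline, climate, rep, mode, t_idx, s_idx
                        )
                    except Exception as exc:  # pragma: no cover - policy path
                        raise RuntimeError(
                            f"replicate failed: transect={tname} scenario={sname} "
                            f"replicate={rep} mode={mode} master_seed={config.master_seed}"
                        ) from exc
                    event_frames.append(
                        engine.events_to_frame(events, rep, sname, mode, tname)
                    )
                    ledger_frames.append(ledger.to_frame(rep, sname, mode, tname))
                    if progress is not None:
                        burned = float(sum(e.realized_size for e in events))
                        progress(
                            f"{tname}/{sname} rep={rep} mode={mode}: "
                            f"{len(events)} fires, {burned:.0f} ha burned"
                        )

    events = pd.concat(event_frames, ignore_index=True)
    ledgers = pd.concat(ledger_frames, ignore_index=True)
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_runs": len(event_frames),
        "transects": [s.name for s in specs],
        "scenarios": sorted(climates),
        "modes": list(config.modes),
        "n_replicates": config.n_replicates,
        "years": [config.start_year, config.end_year],
    }
    return ExperimentResult(events=events, ledgers=ledgers, manifest=manifest)
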