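import numpy as np
import pytest

from firefeedback.engine import (
    DEFAULT_FUEL_MODELS,
    SeverityParams,
    UnknownFuelModelError,
    apply_fire,
    draw_ignitions,
    draw_weather,
    fuel_models_from_frame,
    fuel_models_to_frame,
    ignition_becomes_fire,
    spread_fire,
)
from firefeedback.landscape import ClimateSeries

from .conftest import uniform_landscape


def climate_with(weather_dist):
    years = np.arange(2010, 2100)
    return ClimateSeries("x", years, np.full(90, 150.0), weather_dist)


class TestIgnitions:
    def test_zero_rate_always_empty(self, flat_landscape):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert draw_ignitions(flat_landscape, 0.0, rng) == []

    def test_single_cell_grid_puts_every_ignition_at_origin(self):
        ls = uniform_landscape(n=1)
        rng = np.random.default_rng(1)
        for _ in range(20):
            for cell in draw_ignitions(ls, 1.0, rng):
                assert cell == (0, 0)

    def test_poisson_mean_recovered(self, flat_landscape):
        rng = np.random.default_rng(3)
        counts = [len(draw_ignitions(flat_landscape, 5.0, rng)) for _ in range(10_000)]
        se = np.sqrt(5.0 / 10_000)
        assert abs(np.mean(counts) - 5.0) < 2 * se

    def test_no_repeats_within_a_year(self, flat_landscape):
        rng = np.random.default_rng(4)
        for _ in range(100):
            cells = draw_ignitions(flat_landscape, 30.0, rng)
            assert len(cells) == len(set(cells))


class TestFireProbability:
    def test_zero_base_probability_never_ignites(self, flat_landscape):
        fuels = {"mixed_conifer": DEFAULT_FUEL_MODELS["mixed_conifer"].__class__(
            id="mixed_conifer", ros=1.0, base_fire_prob=0.0)}
        rng = np.random.default_rng(0)
        assert not any(
            ignition_becomes_fire((3, 3), flat_landscape, fuels, 0.9, rng)
            for _ in range(200)
        )

    def test_certain_ignition_under_unit_multiplier(self, flat_landscape):
        fuels = {"mixed_conifer": DEFAULT_FUEL_MODELS["mixed_conifer"].__class__(
            id="mixed_conifer", ros=1.0, base_fire_prob=1.0)}
        rng = np.random.default_rng(0)
        # weather 0.5 with gain 2 -> multiplier exactly 1
        assert all(
            ignition_becomes_fire((3, 3), flat_landscape, fuels, 0.5, rng)
            for _ in range(200)
        )

    def test_empirical_frequency_matches_base_probability(self, flat_landscape):
        fuels = {"mixed_conifer": DEFAULT_FUEL_MODELS["mixed_conifer"].__class__(
            id="mixed_conifer", ros=1.0, base_fire_prob=0.3)}
        rng = np.random.default_rng(11)
        hits = sum(
            ignition_becomes_fire((3, 3), flat_landscape, fuels, 0.5, rng)
            for _ in range(100_000)
        )
        assert abs(hits / 100_000 - 0.3) < 0.005

    def test_sub_threshold_biomass_never_ignites(self, fuel_models):
        ls = uniform_landscape(live=50.0, dead=10.0)  # below 200 g/m2
        rng = np.random.default_rng(0)
        assert not any(
            ignition_becomes_fire((3, 3), ls, fuel_models, 0.99, rng) for _ in range(100)
        )

    def test_unknown_fuel_model_is_configuration_error(self, flat_landscape):
        with pytest.raises(UnknownFuelModelError):
            ignition_becomes_fire((0, 0), flat_landscape, {}, 0.5, np.random.default_rng(0))


class TestWeather:
    def test_degenerate_distribution(self):
        clim = climate_with({"kind": "degenerate", "value": 0.5})
        rng = np.random.default_rng(0)
        assert all(draw_weather(clim, rng) == 0.5 for _ in range(100))

    def test_uniform_draws_pass_ks(self):
        from scipy import stats

        clim = climate_with({"kind": "uniform"})
        rng = np.random.default_rng(8)
        draws = np.array([draw_weather(clim, rng) for _ in range(100_000)])
        d = stats.kstest(draws, "uniform").statistic
        critical_1pct = 1.63 / np.sqrt(len(draws))
        assert d < critical_1pct

    def test_shared_stream_gives_identical_sequences(self):
        clim = climate_with({"kind": "beta", "a": 2.0, "b": 3.0})
        a = [draw_weather(clim, np.random.default_rng(99)) for _ in range(1)]
        r1, r2 = np.random.default_rng(5), np.random.default_rng(5)
        s1 = [draw_weather(clim, r1) for _ in range(500)]
        s2 = [draw_weather(clim, r2) for _ in range(500)]
        assert s1 == s2


class TestSpread:
    def test_single_cell_target(self, flat_landscape, fuel_models):
        ev = spread_fire(flat_landscape, (5, 5), 1.0, 0.5, fuel_models)
        assert ev.burned_cells == [(5, 5)]
        assert ev.realized_size == 1.0

    def test_fuel_limited_truncation_on_isolated_component(self, fuel_models):
        ls = uniform_landscape(n=10, live=0.0, dead=0.0)
        # a 7-cell burnable island
        island = [(2, 2), (2, 3), (2, 4), (3, 2), (3, 3), (4, 2), (4, 3)]
        for r, c in island:
            ls.live_biomass[r, c] = 10000.0
        ev = spread_fire(ls, (3, 3), 50.0, 0.5, fuel_models)
        assert ev.realized_size == 7.0
        assert sorted(ev.burned_cells) == sorted(island)

    def test_homogeneous_grid_reaches_target_exactly(self, fuel_models):
        ls = uniform_landscape(n=20)
        ev = spread_fire(ls, (10, 10), 40.0, 0.5, fuel_models)
        assert ev.realized_size == 40.0
        assert len(set(ev.burned_cells)) == 40

    def test_nonburnable_ignition_gives_empty_event(self, fuel_models):
        ls = uniform_landscape(live=0.0, dead=0.0)
        ev = spread_fire(ls, (3, 3), 10.0, 0.5, fuel_models)
        assert ev.realized_size == 0.0
        assert ev.burned_cells == []

    def test_realized_never_exceeds_target(self, fuel_models):
        rng = np.random.default_rng(21)
        ls = uniform_landscape(n=15)
        # random biomass holes
        holes = rng.random(ls.shape) < 0.4
        ls.live_biomass[holes] = 0.0
        ls.dead_biomass[holes] = 0.0
        for _ in range(50):
            r, c = int(rng.integers(15)), int(rng.integers(15))
            target = float(rng.uniform(0.5, 80))
            ev = spread_fire(ls, (r, c), target, 0.5, fuel_models)
            assert ev.realized_size <= max(target, ls.cell_area)

    def test_burned_set_is_edge_connected(self, fuel_models):
        ls = uniform_landscape(n=20)
        ev = spread_fire(ls, (3, 17), 60.0, 0.7, fuel_models)
        cells = set(ev.burned_cells)
        seen = {ev.ignition}
        frontier = [ev.ignition]
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    nb = (r + dr, c + dc)
                    if nb in cells and nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
        assert seen == cells

    def test_spread_is_deterministic(self, fuel_models):
        ls1, ls2 = uniform_landscape(n=20), uniform_landscape(n=20)
        e1 = spread_fire(ls1, (4, 4), 55.0, 0.3, fuel_models)
        e2 = spread_fire(ls2, (4, 4), 55.0, 0.3, fuel_models)
        assert e1.burned_cells == e2.burned_cells


class TestApplyFire:
    def test_zero_severity_changes_nothing(self, fuel_models):
        ls = uniform_landscape(n=5, dead=0.0)
        before = ls.live_biomass.copy()
        ev = spread_fire(ls, (2, 2), 4.0, 0.5, fuel_models)
        _, ev = apply_fire(ls, ev, fuel_models, SeverityParams(0.0, 0.0, 0.0))
        assert np.array_equal(ls.live_biomass, before)
        assert ev.consumed_dry_biomass == 0.0

    def test_hand_arithmetic_consumption(self, fuel_models):
        # 10 000 g/m2 live on 1 ha, severity forced to 1, live consumption
        # 0.3, empty dead pool -> 10 000 g/m2 * 1e4 m2 * 0.3 = 3.0e4 kg
        ls = uniform_landscape(n=3, live=10000.0, dead=0.0)
        ev = spread_fire(ls, (1, 1), 1.0, 0.5, fuel_models)
        _, ev = apply_fire(ls, ev, fuel_models, SeverityParams(1.0, 0.0, 0.0))
        assert ev.consumed_dry_biomass == pytest.approx(3.0e4)
        assert ev.c_efflux == pytest.approx(1.5e4)
        # killed-but-unconsumed live went to the dead pool
        assert ls.live_biomass[1, 1] == 0.0
        assert ls.dead_biomass[1, 1] == pytest.approx(7000.0)

    def test_mass_balance_identity_per_cell(self, fuel_models):
        rng = np.random.default_rng(17)
        ls = uniform_landscape(n=12)
        ls.live_biomass = rng.uniform(500, 20000, ls.shape)
        ls.dead_biomass = rng.uniform(0, 5000, ls.shape)
        pre = ls.live_biomass + ls.dead_biomass
        ev = spread_fire(ls, (6, 6), 80.0, 0.8, fuel_models)
        _, ev = apply_fire(ls, ev, fuel_models)
        post = ls.live_biomass + ls.dead_biomass
        consumed_gm2 = pre - post
        # burned cells: consumed recorded; unburned: unchanged
        total_kg = consumed_gm2.sum() * 10.0 * ls.cell_area
        assert total_kg == pytest.approx(ev.consumed_dry_biomass, rel=1e-6)
        burned = np.zeros(ls.shape, dtype=bool)
        for r, c in ev.burned_cells:
            burned[r, c] = True
        assert np.allclose(consumed_gm2[~burned], 0.0)
        assert np.all(consumed_gm2[burned] >= 0)

    def test_burned_cells_switch_to_postfire_fuel_and_reset_clock(self, fuel_models):
        ls = uniform_landscape(n=8)
        ev = spread_fire(ls, (4, 4), 9.0, 0.5, fuel_models)
        apply_fire(ls, ev, fuel_models)
        for r, c in ev.burned_cells:
            assert ls.fuel_model[r, c] == "postfire"
            assert ls.time_since_fire[r, c] == 0

    def test_severity_increases_with_weather(self, fuel_models):
        sev = []
        for w in (0.1, 0.5, 0.9):
            ls = uniform_landscape(n=8)
            ev = spread_fire(ls, (4, 4), 9.0, w, fuel_models)
            _, ev = apply_fire(ls, ev, fuel_models)
            sev.append(ev.mean_severity)
        assert sev[0] < sev[1] < sev[2]
        assert all(0.0 <= s <= 1.0 for s in sev)


def test_grass_has_highest_rate_of_spread_among_defaults():
    grass = DEFAULT_FUEL_MODELS["grass"].ros
    assert all(fm.ros <= grass for fm in DEFAULT_FUEL_MODELS.values())


def test_fuel_model_table_roundtrip():
    df = fuel_models_to_frame(DEFAULT_FUEL_MODELS)
    back = fuel_models_from_frame(df)
    assert back == DEFAULT_FUEL_MODELS
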