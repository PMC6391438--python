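import numpy as np
import pandas as pd
import pytest
from scipy import stats

from firefeedback.analysis import (
    PERIODS,
    RangeComposition,
    area_weight_scale,
    cumulative_area_burned,
    paired_sign_test,
    percent_change,
    period_fire_stats,
    welch_log_test,
)


def _events(rows):
    df = pd.DataFrame(rows)
    for col, default in (
        ("scenario", "s"), ("mode", "static"), ("replicate", 0), ("transect", "t")
    ):
        if col not in df.columns:
            df[col] = default
    return df


class TestCumulativeAreaBurned:
    def test_no_fires_is_flat_zero(self):
        df = _events([{"year": 2015, "realized_ha": 0.0}])
        out = cumulative_area_burned(df)
        assert np.allclose(out["mean_km2"], 0.0)
        assert len(out) == 90

    def test_single_fire_steps_and_stays(self):
        df = _events([{"year": 2012, "realized_ha": 100.0}])
        out = cumulative_area_burned(df)
        series = out.set_index("year")["mean_km2"]
        assert series[2010] == 0.0 and series[2011] == 0.0
        assert series[2012] == 1.0  # 100 ha = 1 km2
        assert series[2099] == 1.0
        assert np.all(np.diff(series.to_numpy()) >= 0)

    def test_identical_replicates_have_zero_width_band(self):
        rows = [
            {"year": 2020, "realized_ha": 250.0, "replicate": r} for r in range(4)
        ]
        out = cumulative_area_burned(_events(rows))
        assert np.allclose(out["lo_km2"], out["hi_km2"])
        assert np.allclose(out["mean_km2"], out["lo_km2"])

    def test_band_contains_mean(self, small_result):
        out = cumulative_area_burned(small_result.events)
        assert np.all(out["lo_km2"] <= out["mean_km2"] + 1e-9)
        assert np.all(out["mean_km2"] <= out["hi_km2"] + 1e-9)


class TestPercentChange:
    def test_equal_totals(self):
        assert percent_change(100.0, 100.0) == 0.0

    def test_simple_reduction(self):
        assert percent_change(85.7, 100.0) == pytest.approx(-14.3)

    def test_reduction_relative_to_implied_static_median(self):
        # a 38.3 Tg reduction on a dynamic median of 257.7 Tg is -12.9% of
        # the implied static median (257.7 + 38.3)
        assert percent_change(257.7, 257.7 + 38.3) == pytest.approx(-12.9, abs=0.05)

    def test_zero_static_total_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(10.0, 0.0)


class TestPeriodStats:
    def test_upper_quartile_is_strict_exceedance_set(self):
        rows = [{"year": 2015, "realized_ha": s} for s in (1.0, 2.0, 3.0, 4.0)]
        out = period_fire_stats(_events(rows))
        early = out[(out.period == "early") & (out["mode"] == "static")].iloc[0]
        assert list(early["upper_quartile_sizes"]) == [4.0]

    def test_equal_sizes_give_empty_upper_quartile(self):
        rows = [{"year": 2015, "realized_ha": 7.0} for _ in range(6)]
        out = period_fire_stats(_events(rows))
        early = out[(out.period == "early") & (out["mode"] == "static")].iloc[0]
        assert len(early["upper_quartile_sizes"]) == 0

    def test_replicate_maxima_collected(self):
        rows = [
            {"year": 2015, "realized_ha": 5.0, "replicate": 0},
            {"year": 2016, "realized_ha": 9.0, "replicate": 0},
            {"year": 2017, "realized_ha": 7.0, "replicate": 1},
        ]
        out = period_fire_stats(_events(rows))
        early = out[(out.period == "early") & (out["mode"] == "static")].iloc[0]
        assert sorted(early["replicate_maxima"]) == [7.0, 9.0]

    def test_empty_period_flagged(self):
        rows = [{"year": 2015, "realized_ha": 3.0}]
        out = period_fire_stats(_events(rows))
        late = out[(out.period == "late") & (out["mode"] == "static")].iloc[0]
        assert late["empty"] and late["n_fires"] == 0

    def test_periods_partition_span(self):
        years = sorted(y for lo, hi in PERIODS.values() for y in (lo, hi))
        assert years == [2010, 2039, 2040, 2069, 2070, 2099]


class TestWelch:
    def test_identical_samples(self):
        res = welch_log_test([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert res.t == 0.0 and res.p == 1.0

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            na, nb = rng.integers(5, 200, size=2)
            a = rng.lognormal(rng.normal(), rng.uniform(0.2, 1.5), na)
            b = rng.lognormal(rng.normal(), rng.uniform(0.2, 1.5), nb)
            ours = welch_log_test(a, b)
            ref = stats.ttest_ind(np.log(a), np.log(b), equal_var=False)
            assert ours.t == pytest.approx(ref.statistic, abs=1e-8)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-8)
            assert ours.df == pytest.approx(ref.df, abs=1e-8)

    def test_detects_log_mean_shift(self):
        rng = np.random.default_rng(5)
        a = rng.lognormal(3.0, 0.8, 200)
        b = rng.lognormal(4.0, 0.8, 200)
        assert welch_log_test(a, b).p < 0.001

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            welch_log_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            welch_log_test([1.0, -2.0], [2.0, 3.0])


class TestAreaWeightScale:
    def _means(self, rows):
        return pd.DataFrame(rows, columns=["transect", "veg_type", "mean_per_ha", "area_ha"])

    def test_single_type_covers_range(self):
        comp = RangeComposition({"mixed_conifer": 1.0})
        means = self._means([("t1", "mixed_conifer", 2.5, 1000.0)])
        assert area_weight_scale(means, comp) == pytest.approx(2.5 * 3.4e6)

    def test_two_types_half_and_half(self):
        comp = RangeComposition({"a_low": 0.5, "grass": 0.5})
        means = self._means([("t1", "a_low", 2.0, 100.0), ("t1", "grass", 4.0, 100.0)])
        total = area_weight_scale(means, comp)
        assert total / 3.4e6 == pytest.approx(3.0)  # range mean 3 per ha

    def test_unequal_weights(self):
        comp = RangeComposition({"a": 0.25, "b": 0.75})
        means = self._means([("t1", "a", 0.0, 10.0), ("t1", "b", 4.0, 10.0)])
        assert area_weight_scale(means, comp) / 3.4e6 == pytest.approx(3.0)

    def test_transect_weighting_by_type_area(self):
        comp = RangeComposition({"a": 1.0})
        means = self._means([("t1", "a", 1.0, 300.0), ("t2", "a", 4.0, 100.0)])
        # area-weighted mean = (1*300 + 4*100)/400 = 1.75
        assert area_weight_scale(means, comp) / 3.4e6 == pytest.approx(1.75)

    def test_linearity_and_split_invariance(self):
        comp = RangeComposition({"a": 0.6, "b": 0.4})
        means = self._means([("t1", "a", 2.0, 50.0), ("t1", "b", 5.0, 50.0)])
        base = area_weight_scale(means, comp)
        doubled = self._means([("t1", "a", 4.0, 50.0), ("t1", "b", 10.0, 50.0)])
        assert area_weight_scale(doubled, comp) == pytest.approx(2 * base)
        split_comp = RangeComposition({"a": 0.6, "b1": 0.2, "b2": 0.2})
        split = self._means(
            [("t1", "a", 2.0, 50.0), ("t1", "b1", 5.0, 50.0), ("t1", "b2", 5.0, 50.0)]
        )
        assert area_weight_scale(split, split_comp) == pytest.approx(base)

    def test_missing_type_listed_in_error(self):
        comp = RangeComposition({"a": 0.5, "missing_type": 0.5})
        means = self._means([("t1", "a", 1.0, 10.0)])
        with pytest.raises(KeyError, match="missing_type"):
            area_weight_scale(means, comp)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            RangeComposition({"a": 0.5, "b": 0.4})


class TestSignTest:
    def test_clear_direction(self):
        wins, n, p = paired_sign_test([1, 1, 1, 1, 1, 1, 1, 1], [2, 2, 2, 2, 2, 2, 2, 2])
        assert wins == 8 and n == 8 and p == pytest.approx(0.5**8)

    def test_ties_are_dropped(self):
        wins, n, p = paired_sign_test([1.0, 2.0], [1.0, 3.0])
        assert (wins, n) == (1, 1)
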