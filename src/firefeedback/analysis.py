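"""Statistical comparison of static and dynamic simulations.

Covers the experiment's analysis surface: cumulative area burned with
replicate percentile bands, period-stratified fire-size statistics
(upper-quartile subsets and per-replicate maxima), Welch two-sample t-tests
on log-transformed fire sizes, percent-change summaries, and area-weighted
scaling of per-vegetation-type transect means to a full mountain range of
3.4 million ha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PERIODS",
    "RANGE_AREA_HA",
    "RangeComposition",
    "WelchResult",
    "cumulative_area_burned",
    "percent_change",
    "period_of_year",
    "period_fire_stats",
    "welch_log_test",
    "area_weight_scale",
    "paired_sign_test",
]

#: Time periods partitioning the simulation span.
PERIODS = {"early": (2010, 2039), "mid": (2040, 2069), "late": (2070, 2099)}

#: Full mountain-range area (ha) used by area-weighted scaling.
RANGE_AREA_HA = 3.4e6

HA_PER_KM2 = 100.0


def period_of_year(year: int, periods=None) -> str:
    periods = periods or PERIODS
    for name, (lo, hi) in periods.items():
        if lo <= year <= hi:
            return name
    raise KeyError(f"year {year} falls in no period")


def cumulative_area_burned(
    events: pd.DataFrame,
    start_year: int = 2010,
    end_year: int = 2099,
    by: str = "all",
) -> pd.DataFrame:
    """Annual cumulative burned area (km2) with replicate mean and band.

    Returns one row per (group, mode, year) with ``mean_km2``, ``lo_km2`` and
    ``hi_km2``, where the band is the empirical 2.5th/97.5th percentile
    across replicate cumulative series (scenarios pooled into the replicate
    set).  ``by`` is ``"all"`` (pool transects) or ``"transect"``.
    """
    years = np.arange(start_year, end_year + 1)
    if by == "all":
        groups = [("all", events)]
    elif by == "transect":
        groups = list(events.groupby("transect"))
    else:
        raise ValueError("by must be 'all' or 'transect'")

    rows = []
    for gname, gdf in groups:
        for mode, mdf in gdf.groupby("mode"):
            series = []
            for (_, _), rdf in mdf.groupby(["scenario", "replicate"]):
                annual = (
                    rdf.groupby("year")["realized_ha"].sum().reindex(years, fill_value=0.0)
                )
                series.append(np.cumsum(annual.to_numpy()) / HA_PER_KM2)
            if not series:
                continue
            arr = np.vstack(series)
            mean = arr.mean(axis=0)
            if arr.shape[0] >= 2:
                lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
            else:
                lo = hi = mean
            for i, y in enumerate(years):
                rows.append(
                    {
                        "group": gname,
                        "mode": mode,
                        "year": int(y),
                        "mean_km2": mean[i],
                        "lo_km2": lo[i],
                        "hi_km2": hi[i],
                    }
                )
    return pd.DataFrame(rows)


def percent_change(dynamic_total: float, static_total: float) -> float:
    """Percent change of the dynamic total relative to the static total."""
    if static_total == 0:
        raise ZeroDivisionError("percent change undefined for zero static total")
    return 100.0 * (dynamic_total - static_total) / static_total


def period_fire_stats(events: pd.DataFrame, periods=None) -> pd.DataFrame:
    """Per (period, mode) fire-size statistics.

    ``upper_quartile_sizes`` holds the strict exceedances of the period's
    (type-7, linear-interpolation) 75th percentile; ``replicate_maxima`` the
    maximum fire size of each (scenario, replicate) run in the period.
    Fires are pooled across transects, scenarios and replicates.
    """
    periods = periods or PERIODS
    df = events.copy()
    df["period"] = [period_of_year(y, periods) for y in df["year"]]
    rows = []
    for period in periods:
        for mode in sorted(df["mode"].unique()):
            sub = df[(df["period"] == period) & (df["mode"] == mode)]
            sizes = sub["realized_ha"].to_numpy(dtype=float)
            if len(sizes) == 0:
                rows.append(
                    {
                        "period": period,
                        "mode": mode,
                        "n_fires": 0,
                        "mean_ha": np.nan,
                        "q75_ha": np.nan,
                        "upper_quartile_sizes": np.array([]),
                        "replicate_maxima": np.array([]),
                        "empty": True,
                    }
                )
                continue
            q75 = float(np.percentile(sizes, 75))  # linear interpolation
            maxima = (
                sub.groupby(["scenario", "replicate"])["realized_ha"].max().to_numpy()
            )
            rows.append(
                {
                    "period": period,
                    "mode": mode,
                    "n_fires": len(sizes),
                    "mean_ha": float(sizes.mean()),
                    "q75_ha": q75,
                    "upper_quartile_sizes": sizes[sizes > q75],
                    "replicate_maxima": maxima,
                    "empty": False,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_log_test(sizes_a, sizes_b) -> WelchResult:
    """Welch two-sample t-test on natural-log fire sizes.

    Unequal-variance t statistic with Welch-Satterthwaite degrees of
    freedom and a two-sided p-value.  Sizes must be positive and each
    sample must have at least two observations.
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two fire sizes")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("fire sizes must be positive for the log transform")
    la, lb = np.log(a), np.log(b)
    na, nb = len(la), len(lb)
    va, vb = la.var(ddof=1), lb.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0)
    t = (la.mean() - lb.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


@dataclass(frozen=True)
class RangeComposition:
    """Vegetation-type area fractions of the full mountain range."""

    fractions: dict
    total_area_ha: float = RANGE_AREA_HA

    def __post_init__(self):
        total = sum(self.fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"composition fractions must sum to 1, got {total}")


def area_weight_scale(per_transect_means: pd.DataFrame, composition: RangeComposition) -> float:
    """Scale per-vegetation-type transect means to the full mountain range.

    ``per_transect_means`` needs columns ``transect``, ``veg_type``,
    ``mean_per_ha`` (any per-ha quantity) and ``area_ha`` (the transect area
    of that type, used to weight transects).  The range total is

        sum_type [ area-weighted mean_per_ha of the type across transects ]
                 x fraction_type x total range area.
    """
    missing = [
        v for v in composition.fractions if v not in set(per_transect_means["veg_type"])
    ]
    if missing:
        raise KeyError(f"no transect mean for vegetation type(s): {missing}")
    total = 0.0
    for veg, frac in composition.fractions.items():
        sub = per_transect_means[per_transect_means["veg_type"] == veg]
        w = sub["area_ha"].to_numpy(dtype=float)
        v = sub["mean_per_ha"].to_numpy(dtype=float)
        if w.sum() <= 0:
            raise ValueError(f"vegetation type {veg!r} has zero transect area")
        mean = float(np.average(v, weights=w))
        total += mean * frac * composition.total_area_ha
    return total


def paired_sign_test(dynamic_values, static_values) -> tuple[int, int, float]:
    """One-sided sign test that dynamic < static across paired replicates.

    Returns (number of pairs with dynamic < static, number of non-tied
    pairs, one-sided binomial p-value).
    """
    d = np.asarray(dynamic_values, dtype=float)
    s = np.asarray(static_values, dtype=float)
    if d.shape != s.shape:
        raise ValueError("paired samples must have equal length")
    diffs = d - s
    non_tied = int(np.sum(diffs != 0))
    wins = int(np.sum(diffs < 0))
    if non_tied == 0:
        return 0, 0, 1.0
    p = stats.binomtest(wins, non_tied, 0.5, alternative="greater").pvalue
    return wins, non_tied, float(p)
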