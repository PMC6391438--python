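"""Figures and tables summarizing a paired experiment.

Produces the standard report set from an :class:`ExperimentResult`:
cumulative-burned-area curves with replicate bands, box summaries of
upper-quartile and maximum fire sizes by period with significance
asterisks, an interquartile emissions table, and total-ecosystem-carbon
trajectories.  All outputs are plain files (PNG figures, CSV/text tables).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import analysis
from .emissions import EMISSION_FACTORS, aggregate_emissions, round_half_up

__all__ = ["build_reports", "emissions_table_text"]

# caption-style significance thresholds
QUARTILE_ALPHA = 0.001
MAXIMA_ALPHA = 0.01


def emissions_table_text(summary: pd.DataFrame) -> str:
    """Interquartile-range emissions table (Tg, one decimal, half-up)."""
    lines = ["Constituent  Dynamic (Tg)     Static (Tg)"]
    for sp in EMISSION_FACTORS:
        row = {"dynamic": "-", "static": "-"}
        for mode in ("dynamic", "static"):
            sub = summary[(summary["species"] == sp) & (summary["mode"] == mode)]
            if len(sub):
                q25 = sum(sub["q25_tg"])
                q75 = sum(sub["q75_tg"])
                row[mode] = f"{round_half_up(q25):.1f}-{round_half_up(q75):.1f}"
        lines.append(f"{sp:<12} {row['dynamic']:<16} {row['static']}")
    return "\n".join(lines) + "\n"


def _boxplot(ax, stats_df: pd.DataFrame, value_col: str, alpha: float, title: str):
    periods = list(analysis.PERIODS)
    positions, data, labels = [], [], []
    stars = []
    for i, period in enumerate(periods):
        sub = {
            mode: row
            for mode, row in (
                (r["mode"], r)
                for _, r in stats_df[stats_df["period"] == period].iterrows()
            )
        }
        for j, mode in enumerate(("static", "dynamic")):
            vals = np.asarray(sub[mode][value_col]) if mode in sub else np.array([])
            data.append(vals if len(vals) else [np.nan])
            positions.append(i * 3 + j)
            labels.append(f"{period}\n{mode}")
        if "static" in sub and "dynamic" in sub:
            s, d = sub["static"][value_col], sub["dynamic"][value_col]
            if len(s) >= 2 and len(d) >= 2:
                res = analysis.welch_log_test(
                    np.clip(s, 1e-9, None), np.clip(d, 1e-9, None)
                )
                if res.p < alpha and np.mean(np.log(s)) > np.mean(np.log(d)):
                    stars.append(i * 3 + 0.5)
    ax.boxplot(data, positions=positions, widths=0.8)
    top = max((np.nanmax(np.concatenate([np.atleast_1d(d) for d in data])), 1.0))
    for x in stars:
        ax.text(x, top * 1.02, "*", ha="center", fontsize=14)
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("fire size (ha)")
    ax.set_title(title)


def build_reports(result, outdir) -> dict:
    """Write the full report set; returns {name: path}.

    Refuses empty results (no fires at all) with a clear message.
    """
    if result.events.empty:
        raise ValueError(
            "cannot build reports from an experiment with no fire events"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    years = result.manifest.get("years", [2010, 2099])

    # cumulative area burned curves (per transect and pooled)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, by in zip(axes, ("all", "transect")):
        cum = analysis.cumulative_area_burned(result.events, years[0], years[1], by=by)
        for (group, mode), sub in cum.groupby(["group", "mode"]):
            style = "-" if mode == "static" else "--"
            ax.plot(sub["year"], sub["mean_km2"], style, label=f"{group} {mode}")
            ax.fill_between(sub["year"], sub["lo_km2"], sub["hi_km2"], alpha=0.15)
        ax.set_xlabel("year")
        ax.set_ylabel("cumulative area burned (km$^2$)")
        ax.legend(fontsize=6)
    fig.tight_layout()
    p = outdir / "cumulative_area_burned.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["cumulative_area_burned"] = p

    # period-stratified fire-size boxes
    stats_df = analysis.period_fire_stats(result.events)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    _boxplot(
        axes[0], stats_df, "upper_quartile_sizes", QUARTILE_ALPHA,
        "upper-quartile fire sizes",
    )
    _boxplot(axes[1], stats_df, "replicate_maxima", MAXIMA_ALPHA, "maximum fire sizes")
    fig.tight_layout()
    p = outdir / "fire_size_periods.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["fire_size_periods"] = p

    # emissions IQR table
    summary = aggregate_emissions(result.events)
    summary.to_csv(outdir / "emissions_summary.csv", index=False)
    paths["emissions_summary"] = outdir / "emissions_summary.csv"
    # pooled-over-scenario table in the printed style
    pooled = aggregate_emissions(
        result.events.assign(scenario="all"),
    )
    table = emissions_table_text(pooled)
    p = outdir / "emissions_table.txt"
    p.write_text(table)
    paths["emissions_table"] = p

    # TEC trajectories
    fig, ax = plt.subplots(figsize=(6, 4))
    tec = (
        result.ledgers.groupby(["mode", "year"])["tec_kg"].mean().reset_index()
    )
    for mode, sub in tec.groupby("mode"):
        ax.plot(sub["year"], sub["tec_kg"] / 1e9, label=mode)
    ax.set_xlabel("year")
    ax.set_ylabel("total ecosystem carbon (Tg C)")
    ax.legend()
    fig.tight_layout()
    p = outdir / "tec_trajectories.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths["tec_trajectories"] = p

    return paths
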