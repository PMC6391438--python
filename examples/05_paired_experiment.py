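"""Run a reduced paired static/dynamic experiment and summarize the feedback.

One transect, two climate scenarios, four replicates on a 60x60 grid — a
few-second version of the full default experiment.  The printed numbers are
the experiment's core result: how much the vegetation-fire feedback (prior
burns limiting fuel) moderates projected burned area.
"""

import firefeedback as ff

config = ff.ExperimentConfig(
    n_rows=60,
    n_cols=60,
    n_replicates=4,
    transect_names=("north",),
    scenarios={
        "climA": {"trend": 25.0, "noise_sd": 25.0, "base": 150.0},
        "climB": {"trend": 30.0, "noise_sd": 25.0, "base": 160.0},
    },
)
result = ff.run_experiment(config)

cum = (
    result.events.groupby(["scenario", "replicate", "mode"])["realized_ha"]
    .sum()
    .unstack("mode")
)
pct = ff.percent_change(cum["dynamic"].mean(), cum["static"].mean())
wins, n, p = ff.paired_sign_test(cum["dynamic"], cum["static"])

print(f"mean cumulative burned, static : {cum['static'].mean():8.0f} ha")
print(f"mean cumulative burned, dynamic: {cum['dynamic'].mean():8.0f} ha")
print(f"feedback effect: {pct:+.1f}% (negative = prior burns limit later fires)")
print(f"paired sign test: dynamic lower in {wins}/{n} pairs, one-sided p = {p:.2g}")

late = result.events[result.events.year >= 2070]
m = late.groupby("mode")["realized_ha"].mean()
print(f"late-century (2070-99) mean fire size: dynamic {m['dynamic']:.0f} ha "
      f"vs static {m['static']:.0f} ha")

first = result.events[result.events.year < 2020]
f = first.groupby("mode")["realized_ha"].sum()
print(f"first-decade burned area, dynamic - static: {f['dynamic'] - f['static']:.0f} ha "
      "(identical by construction: the modes share random streams and only "
      "diverge after the first decadal re-estimation)")
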