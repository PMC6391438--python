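# firefeedback

Fire is self-limiting: a burn removes fuel, and until vegetation regrows,
later fires that reach the same ground stay smaller. Climate-driven
projections of area burned that ignore this feedback can overstate future
fire, carbon loss and smoke emissions. `firefeedback` is a desk-scale
stochastic simulator for quantifying that overstatement: it runs paired
simulations of a fire-prone mountain landscape in which large-fire size
distributions are either a function of projected climate alone (**static**)
or of climate *and* the biomass left behind by the previous decade's fires
(**dynamic**), and measures how much accounting for prior burns moderates
projected burned area, ecosystem carbon and emissions.

It is written for landscape fire ecologists and carbon modellers who want a
transparent, fully testable stand-in for heavyweight forest-landscape
simulators when studying the vegetation-fire feedback itself.

## The model

**Fire sizes.** Large wildfires (> *u* = 200 ha) follow a peaks-over-
threshold model: the log exceedance *y* = log(size/*u*) is generalized
Pareto,

    y | D, B ~ GPD(ξ, σ(D, B)),      log σ = a₀ + a₁·D + a₂·B,

where *D* is the year's cumulative monthly moisture deficit (mm) and *B*
the aboveground live biomass (g/m²) in the 3×3 neighborhood of the
ignition. The shape ξ is constant; conditioning enters through the scale.
Fires at or below *u* come from a lognormal small-fire distribution.

**The feedback.** Each simulated decade, the dynamic arm re-estimates the
conditional size distributions by feeding the prior decade's fire-impacted
biomass layer into the model as its biomass input; the static arm keeps the
historic biomass. Both arms share identical ignition, weather and
fire-probability random streams, so the *only* difference between a pair is
what prior fire did to fuel.

**Everything else.** Poisson ignitions; per-fuel-model fire probabilities
scaled by a fire-weather percentile; frontier-growth spread (annex the
highest-score neighbor, score = rate-of-spread × weather ÷ distance) until
the drawn target size is reached or burnable fuel runs out; severity rising
with fuel load and weather; exact per-fire dry-mass balance; logistic
regrowth toward per-vegetation carrying capacities; carbon ledger with
TEC = (live + dead) × 0.5; FINN emissions (species = dry biomass burned ×
emission factor: CO₂ 1454, CO 89.3, CH₄ 4.9, PM1 26, OA 24.3 g/kg).

All inputs are synthetic and seeded: three mountain transects spanning
printed elevation ranges (south 290–4388 m, central 252–3978 m, north
275–2591 m) with elevation-zoned vegetation, and 2010–2099 moisture-deficit
series with warming trends standing in for downscaled climate projections.

## Worked example

`examples/05_paired_experiment.py` runs a reduced paired experiment (one
transect, two climate scenarios, four replicates, 60×60 grid) and prints:

```
mean cumulative burned, static :    18577 ha
mean cumulative burned, dynamic:    17176 ha
feedback effect: -7.5% (negative = prior burns limit later fires)
paired sign test: dynamic lower in 8/8 pairs, one-sided p = 0.0039
late-century (2070-99) mean fire size: dynamic 159 ha vs static 173 ha
first-decade burned area, dynamic - static: 0 ha (identical by construction: ...)
```

Read it as: over 2010–2099 the static arm burns 18 577 ha of the 3 600 ha
transect (the landscape re-burns as fuels recover); accounting for prior
burns trims that by 7.5%, consistently across all replicate pairs; the
effect is concentrated in late-century fire sizes and is exactly zero
before the first decadal re-estimation, because until then the two arms
are bit-identical.

The other examples each demonstrate one capability: landscape/climate
generation (`01`), fitting and sampling the conditional GPD with
profile-likelihood intervals (`02`), fuel-limited spread with a mass-balance
audit (`03`), and the emissions algebra (`04`).

```python
import firefeedback as ff

result = ff.run_experiment(ff.ExperimentConfig())     # full default design
ff.build_reports(result, "reports/")                  # figures + tables
```

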