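# Methods

This note documents the model, its parameters and defaults, the synthetic
data the package runs on, and the numerical and design choices behind the
implementation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The paired experiment

The unit of inference is a **pair** of simulations on the same transect,
climate scenario and replicate seed. Both members run the identical annual
loop — Poisson ignitions, fire-probability and fire-weather draws, a
fire-size draw, frontier spread, fire effects, logistic regrowth, carbon
accounting — and share the same five named random substreams (ignition,
weather, fire-probability, fire-size, small-fire), derived from the master
seed via `numpy.random.SeedSequence` spawn keys that do not include the
mode. The only difference is the decadal re-estimation step:

* **static** — the fire-size model and its biomass input stay at their
  baseline (historic) state for all 90 years;
* **dynamic** — at every 10-year boundary the conditional fire-size
  distributions are re-estimated by replacing their biomass input with the
  current, fire-impacted live-biomass raster (a decadal snapshot used for
  all draws of the following decade).

Consequences that the tests assert: the first decade of a pair is
bit-identical; with the biomass coefficient forced to zero the *entire*
pair is bit-identical; and any static/dynamic difference is attributable to
what prior fire did to fuel.

### Why re-estimation updates the input, not the coefficients

The alternative — re-fitting the GPD coefficients against the historic fire
sizes after overwriting the historic biomass covariates with current values
— is self-defeating: the response was generated by the *historic* biomass,
so a maximum-likelihood refit re-absorbs any uniform biomass displacement
into the intercept exactly (the likelihood only sees the covariate up to
its empirical location), attenuates partial displacement, and injects
refit noise that inflates the heavy-tailed size draws. In trial runs that
variant produced *more* burned area in the dynamic arm. The implemented
semantics — coefficients estimated once from the historic catalogue,
biomass input updated decadally — is the standard covariate-projection use
of a fitted conditional model, and is the only variant under which "less
fuel ⇒ smaller fires" survives estimation.

## Fire-size model

For fires above the threshold *u* = 200 ha, y = log(size/u) ~ GPD(ξ, σ)
with log σ = a₀ + a₁·D + a₂·B. Choices:

* **Log link** guarantees σ > 0 for all covariate values.
* **Constant ξ** keeps fits stable at the few-hundred-exceedance
  catalogues used here; conditioning enters through σ only.
* **B = 3×3 neighborhood mean of live biomass** at the ignition cell: a
  local fuel summary that the decadal update can recompute on the
  simulated raster.
* **Fitting**: L-BFGS-B on the negative log-likelihood in a standardized
  covariate space (deficit and biomass differ by two orders of magnitude),
  three deterministically jittered restarts, best likelihood wins; ξ is
  box-constrained to [−0.45, 1]. At least 30 exceedances are required.
* **Uncertainty**: profile-likelihood intervals (χ²₁ cutoff, bisection on
  the profiled deviance), computed in a non-centered scaled design so each
  bound maps back to raw units by a pure rescaling. Calibration is checked
  per parameter: across 20 seeded synthetic catalogues of 400 exceedances,
  each of (ξ, a₀, a₁, a₂) must be covered by its 95% interval in ≥ 18
  sets. Per-parameter coverage is the meaningful check here; demanding all
  four parameters inside simultaneously in 18/20 sets would fail even a
  perfectly calibrated fitter (joint coverage ≈ 0.95⁴ under independence).
* **Sub-threshold fires** are lognormal (meanlog 2.5, sdlog 1.0, clipped
  to [1 ha, u]); the GPD covers only the large-fire tail, and a drawn fire
  is "large" with probability 0.2.

Default generating parameters for the synthetic 1984–2014 catalogue (300
records per transect): ξ = 0.15, a₀ = −1.7, a₁ = 0.002 /mm,
a₂ = 7×10⁻⁵ /(g/m²). a₁ and a₂ set the strength of the climate trend and
of the fuel feedback; with the default climate trends they place the
dynamic-vs-static reduction in cumulative burned area in the
high-single-digit to mid-teens percent range with no early-century
difference — the qualitative regime the experiment is designed to exhibit.
These are declared defaults of the synthetic study conditions, not
estimates of any real landscape.

## Fire engine

* **Ignitions**: Poisson(6/yr) expected count, uniform cells without
  within-year repetition.
* **Fire probability**: base probability per fuel model (grass 0.40,
  oak woodland 0.25, mixed conifer 0.20, red fir 0.12, sparse 0.05,
  post-fire 0.30) × weather multiplier (2 × weather percentile; unit mean
  under uniform weather), clipped to [0, 1]. Cells under 200 g/m² live+dead
  never ignite. One uniform is consumed per attempt regardless of outcome
  so paired streams stay aligned.
* **Weather**: a percentile in [0, 1] from a configured distribution
  (uniform by default; degenerate and beta supported), shared between the
  members of a pair.
* **Spread**: 8-connected frontier growth; the next cell annexed is the
  frontier cell maximizing rate-of-spread × weather multiplier ÷ Euclidean
  distance from the ignition, ties broken by (row, col) so spread is fully
  deterministic given the draw. Growth stops at the drawn target size
  (floor to whole cells) or when no burnable frontier remains — realized
  size never exceeds the target, and fuel-poor ground truncates fires.
* **Severity**: clip(0.2 + 0.5·weather + 0.25·load/15000, 0, 1), the
  fraction of live biomass killed. Consumption: 30% of killed live (80%
  in grass, 60% post-fire) plus 80% of the dead pool; killed-but-unconsumed
  live moves to the dead pool, making the per-fire dry-mass balance exact.
* **Carbon**: efflux = 0.5 × consumed dry biomass; the emissions module
  inverts the same 0.5, so the engine→emissions round trip is exact.

## Vegetation and carbon

Live biomass follows the closed-form logistic toward per-type carrying
capacities (oak woodland 6 500, mixed conifer 16 000, red fir/subalpine
13 000, alpine-sparse 1 800, grass 600 g/m²) at intrinsic rates 0.05–0.12
/yr for forest types (grass 1.2/yr); cells burned to zero re-seed from a
recolonization floor (50–150 g/m²). These rates give forest recovery times
of a few decades, so fuel limitation is real but short-lived — doubling
the rates demonstrably shrinks the static-dynamic gap (tested). The dead
pool decays at 0.05/yr. Burned cells carry a post-fire fuel model until
12–25 fire-free years (1 for grass) restore the forest model.

The carbon ledger tracks live C, dead C, TEC = (live+dead) × 0.5 and
cumulative emitted C; the identity ΔTEC + Δemitted = net growth C holds to
machine precision every year because net growth is measured from the same
biomass totals the ledger uses.

## Synthetic landscapes and climate

Each transect is a 100×100 grid of 1-ha cells. Elevation is a west–east
gradient plus seeded Gaussian noise (5% of range), rescaled to span the
transect's printed range exactly; vegetation follows four elevation bands
(fractions 0–0.30 oak woodland, 0.30–0.60 mixed conifer, 0.60–0.85 red
fir/subalpine, 0.85–1 alpine-sparse) with a seeded fraction of cells
(8–18%, largest in the north transect, weighted toward low elevation)
converted to nonforest grass. Initial live biomass is lognormal around
type means (CV 0.15); dead starts at 10% of live.

Climate is an annual cumulative moisture-deficit series, 2010–2099:
base + linear trend + Gaussian noise, truncated at zero. The three default
scenarios (trends 15, 20, 30 mm/decade; bases 140–160 mm; noise SD 25 mm)
stand in for three climate models under a common emission pathway.

What the generator does **not** emulate: real topography, spatial climate
fields, species composition, interannual weather autocorrelation, wind or
slope effects on spread, and any coupling between deficit and the weather
percentile. Passing tests therefore demonstrate the internal consistency
and directional behavior of the feedback mechanism, not the magnitude of
any real landscape's response; transect grids are declared stand-ins, as
no grid dimensions exist to reconstruct.

## Analysis conventions

* Cumulative burned area is reported in km² with empirical 2.5/97.5
  percentile bands across replicate series, scenarios pooled.
* Periods: early 2010–39, mid 2040–69, late 2070–99.
* "Upper-quartile fires" are strict exceedances of the period's type-7
  (linear interpolation) 75th percentile; fires pool across replicates,
  with per-replicate maxima kept separately.
* Fire-size comparisons use a Welch two-sample t-test on natural-log
  sizes (Satterthwaite df), implemented directly and cross-checked against
  `scipy.stats.ttest_ind(equal_var=False)` to 10⁻⁸; its type-I error is
  verified to sit in [0.035, 0.065] over 1000 seeded null simulations.
* Figure significance markers use p < 0.001 for upper-quartile
  distributions and p < 0.01 for maxima.
* Area-weighted scaling multiplies each vegetation type's
  transect-area-weighted per-ha mean by its range fraction and the total
  range area (3.4×10⁶ ha).
* The directional acceptance check uses the paired sign test over the 30
  (scenario, replicate) pairs of the default design, cumulative burned
  area summed over the three transects.

## Problem sizes and determinism

The default experiment (3 transects × 3 scenarios × 10 replicates × 2
modes × 90 years on 100×100 grids) runs in about a minute on one CPU and
is the size used by both the test suite and the acceptance script; the
examples use smaller single-transect designs. Every output is a pure
function of (config, master seed); reruns are byte-identical.

## Known limitations

* The biomass covariate affects only the size draw and spread truncation;
  there is no per-cell fire-size distribution surface, spatial covariance,
  suppression, wind or slope.
* One fire-weather percentile per ignition; no within-fire weather
  evolution.
* Replicate landscapes share one initial raster per transect; variability
  across replicates is purely stochastic, not parametric.
* The small-fire distribution is static; only large fires feel climate
  and the feedback directly.
* With the default severity response, post-fire live biomass usually stays
  above the burnable threshold, so self-limitation acts mostly through
  smaller size draws rather than outright unburnable ground; engineered
  landscapes in the tests exercise the hard-truncation path explicitly.
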