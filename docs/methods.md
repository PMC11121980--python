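# Methods

This note records the models, conventions and design choices behind
windtrace, and what the synthetic generators do and do not emulate.

## Trajectory model

Virtual moths are passive tracers of the horizontal wind: no airspeed, no
heading, no vertical motion. Each release produces one trajectory per fixed
flight altitude (default 100, 200, …, 1000 m above ground level), stepped
with forward Euler at a 10-min step:

* forward: `x_{i+1} = x_i + v(x_i, t_i) Δt`, from the take-off instant to
  the landing deadline;
* backward: `x_{i+1} = x_i − v(x_i, t_i) Δt` with time decreasing from the
  landing deadline toward take-off (time reversal through the stored
  fields; no adjoint machinery).

Metres convert to degrees with 110,574 m per degree latitude and
111,320 · cos(lat) m per degree longitude, evaluated at the current
latitude each step. At single-night scales (≤ 700 km) the planar
approximation error is far below the meteorological uncertainty, so no
great-circle refinement is used. A midpoint (RK2) integrator is available
for sensitivity checks; all shipped analyses use Euler with the 10-min
step.

**Temperature gate.** Flight requires ambient temperature above a
threshold, default 13.1 °C (the *S. frugiperda* flight threshold, adopted
for *S. litura* on biological similarity). By default the gate applies at
the release point and time only — a cold release yields a single-point
trajectory (`temperature_stop`) — because migration *initiation* is what
the threshold describes. A `continuous` mode also terminates a flight the
first time a sampled temperature drops below threshold, since the original
protocol is ambiguous on this point; the default is `takeoff_only`.

**Termination.** Exactly one of `window_end` (window exhausted),
`boundary_exit` (the next proposed position would leave the grid hull; the
last inside point is kept — this is what piles endpoints up along the
domain edge in plotted trajectory maps), or `temperature_stop`. No recorded
point ever lies outside the domain.

## Atmosphere

Fields live on a regular (time × height-AGL × lat × lon) grid, typically
hourly and ~10 km. Sampling is quadrilinear (multilinear) interpolation —
exact at nodes, a convex combination of the 16 enclosing corners — the
simplest scheme consistent with the data density; how the original
trajectory system interpolated between hourly outputs is unpublished, so
multilinear is this package's documented choice. Heights are metres above
ground (terrain-following conversion from pressure levels is upstream
preprocessing); longitudes are stored in [−180, 180) with no antimeridian
support; temperatures are °C internally, Kelvin converted on read from the
units attribute. I/O is CF-style NetCDF (classic format via the scipy
backend); descending coordinate axes are normalised to ascending on read.

The synthetic monsoon generator produces a uniform southwesterly (spring)
or northeasterly (autumn) flow of configurable speed, a linear temperature
lapse (default 0.65 °C / 100 m), and an optional smooth seeded perturbation
capped at 30 % of the mean component so the component signs — hence the
transport direction — are preserved. It emulates the *directional* regime
of the monsoon reversal, not fronts, shear, diurnal boundary-layer cycles
or terrain channelling; trajectory tests passing on these fields validate
the integrator and its rules, not any real-world route.

## Solar windows

Sunrise/sunset use the standard NOAA solar-position geometry (declination
and equation of time from the Julian-century polynomials) at zenith
90.833°, iterated at the event time, at sea level; site-elevation
correction is off by default. The nightly flight window is
sunset + 20 min → next sunrise − 10 min, the peak take-off and landing
times of migrating noctuids; both offsets are configurable and hold
exactly by construction. Computation keeps seconds; rounding to minutes is
presentation only.

The study's published window times came from a third-party almanac website
whose convention (reference point, refraction model) is unknown; our
computation lands about 10 min from those printed times at the study
coordinates. They are therefore kept as fixtures with a ±15 min tolerance,
not exact oracles. The independent test oracle is the NOAA low-precision
Fourier-series ephemeris, a genuinely different formulation; its truncation
error grows toward high latitudes, so the 2-minute agreement grid spans the
tropical/subtropical band (|lat| ≤ 35°) where nocturnal moth migration is
simulated.

## Region attribution

Containment is closed (boundary points belong to the polygon) and resolved
by explicit priority order; unclassified points fall into `other`.
Point-in-polygon testing is delegated to shapely's `covers`; the test suite
cross-checks it against a hand-written winding-number oracle on random
simple polygons. By default only trajectory *endpoints* are attributed
(whether the original analysis pooled all 10-min points is unstated; the
table metadata records the mode used). Percentages are rounded half-up to
one decimal, and derived aggregates sum the *rounded* member percentages —
matching how derived shares are quoted from a printed table. Season labels
come from the release date: April–May = spring, October–December = autumn
(the k = 4 segmentation of monthly catches), otherwise transition.

The shipped rectangles labelled China/Myanmar/India/Bangladesh are
synthetic fixtures chosen only to be disjoint and correctly arranged around
the study site; real national boundaries are user-supplied GeoJSON.

## Trap statistics

* **Monthly summary**: nightly female counts are summed per (year, month);
  means and standard errors are across years; the female percentage is the
  across-year mean of yearly 100·F/(F+M). The grand total is the sum of the
  12 monthly means (mean females per year).
* **Sex ratio**: two-cell Pearson chi-square against 1:1,
  χ² = (F−M)²/(F+M), 1 df, no continuity correction by default (a Yates
  flag exists). p-values below the double-precision floor report as 0.
* **Optimal partitioning of ordered samples** (Fisher): exact DP over all
  contiguous k-partitions minimising total within-class sum of squared
  deviations. Default preprocessing is z-score standardization; the error
  function is the raw within-class SS of the standardized series. The
  commercial package used originally (DPS) does not document its
  normalisation, so its printed error values are not comparable constants;
  correctness is instead established against exhaustive enumeration (all
  contiguous partitions at small n — e.g. the 165 4-partitions of a
  12-month series). Ties break toward the leftmost boundaries (ascending
  split scan with strict improvement); a constant series skips
  standardization with a warning and returns error 0 with boundaries
  [1, …, k−1]. The scan's suggested k is the largest relative error drop.
* **Ovary summaries**: matured = ovarian level > 2 on the five-level scale
  (1 transparent/opalescent … 5 terminal); mated = ≥ 1 spermatophore; means
  are over dissected females per period.

Daily-vs-monthly granularity for segmentation is a caller choice (the CLI
exposes both); monthly is the default reporting granularity.

## Synthetic trap-catch generator

Nightly totals are negative binomial (overdispersion is universal in trap
counts; size parameter default 2, Poisson recoverable as size → ∞) around a
seasonal mean = baseline + two Gaussian day-of-year bumps with wraparound.
Defaults are the study-like regime: baseline 5 moths/night, spring bump
(centre day 120 ≈ 30 April, σ = 18 d, amplitude 50 = 10× baseline — spring
is the dominant migration), autumn bump (centre day 310 ≈ 6 November,
σ = 25 d, amplitude 20). Females are binomial with the month's female
fraction (defaults = the published monthly percentages, peaking at 60.4 %
in April); up to 20 females per night are "dissected" (the field protocol's
cap), drawing an ovary level from a period-specific multinomial and a
mating count as Bernoulli(mated) × zero-truncated Poisson. The period
multinomials are parameterised so the seeded matured/mated rates equal the
published spring (92.3 % / 83.3 %) and autumn (74.2 % / 62.9 %) values;
recovering them from generated data is a pipeline test, with a
transition-period setting (matured ≈ 87 %, mated 88 %) interpolating the
annual pattern.

The generator emulates marginal distributions and seasonality only: no
night-to-night autocorrelation, no weather-driven trap outages, no
moon-phase efficiency cycles, no interannual trend. Tests passing on it
show the *statistics* are computed correctly under the assumed structure,
not that real trap data meet those assumptions.

## Pipeline and problem sizes

The demo pipeline runs the ten peak migration nights (2019–2023, one spring
and one autumn night per year) in both directions over per-night synthetic
monsoon fields (49 × 6 × 17 × 19 grid, ±8° / ±9° around the site), then the
full trap-statistics workflow on a generated multi-year series. Outputs are
manifest-tracked (config hash + SHA-256 per file); identical configs
reproduce byte-identical outputs. The acceptance script uses endpoint
clouds of n = 1000 per table column (the size at which one-decimal
percentages are exactly realisable), the default 5-year generator (~2000–
4000 dissections per migration period), and 100 seeds for the segmentation
recovery rate; it completes in seconds.

## Known limitations

* No self-powered flight vector, vertical motion, landing-probability
  model, or multi-night trajectory chaining; simulated paths are wind
  transport within one night's window.
* Grid times and flight windows must share one clock (use site-local
  fields or shift windows to UTC upstream); no DST or time-zone database.
* The published study-scale numbers that depend on its real WRF meteorology
  and unpublished raw catches (actual attribution percentages, catch
  totals, figure data) are outside what synthetic inputs can reproduce;
  the pipeline covers them structurally and via the printed-table
  round-trips described above.
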