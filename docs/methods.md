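# Methods

This note documents the models, the synthetic data, the numerical
choices and the limitations of the `portmort` pipeline.

## Study design being emulated

The pipeline reproduces a small-area ecological design: a city of
~100,000 residents divided into 722 census tracts (~139 residents
each), annual-mean pollutant surfaces from a dispersion model on a
0.5 × 0.5 km grid, cause-specific death counts aggregated per tract
over a 5-year window, and a harbour/non-harbour stratification by an
800 m buffer around the port centroid chosen so the harbour stratum
holds at least 10% of the population.  The analysis chain is: exposure
assignment → descriptive stratification → Poisson regression with a
three-level adjustment ladder → WHO-AQG counterfactual health impact
assessment.

## Exposure assignment (zonal statistics)

Each tract's exposure is the area-weighted mean of all raster cells it
overlaps.  The weights are exact intersection areas: the tract polygon
is clipped against each candidate cell rectangle with
Sutherland–Hodgman passes over the four half-planes and the clipped
ring's area comes from the shoelace formula.  Properties that follow
and are tested: the mean is bounded by the participating cell values,
linear in the grid, translation-equivariant, and exact on grid-aligned
rectangles.  NODATA cells are excluded from numerator and denominator
(renormalisation), and tracts with valid-cell coverage below 99% are
flagged.  Polygons must be simple exterior rings in planar metres — no
holes, no CRS handling; that is the documented input contract.  An
independent rasterisation oracle (subcell point-in-polygon counting)
verifies the exact computation in tests; shapely's intersection areas
provide a second independent check of the clipping primitive.

Normalisation uses the intersection area with the valid cells rather
than the tract area; the two coincide whenever coverage is complete,
which the coverage flag monitors.

## Regression

Counts per (tract × age-sex stratum) are modelled as Poisson with log
link and `log(person-years)` offset, person-years = stratum population
× 5 years with a static population (the simplest reading of a
population denominator).  Adjustment levels: (1) intercept + exposure;
(2) + nine indicators for the 10 age-sex strata (reference 35–64
male); (3) + five deprivation indicators (reference `very_high`,
missing kept as its own level).  If a nominal reference category is
absent from the data, a present category is substituted so the block
stays full rank; changing references does not move the exposure
estimate (tested).  Aggregating rows that share covariates leaves the
likelihood unchanged, so level-1 fits on stratum rows equal fits on
tract totals.

The optimiser is Fisher scoring (IRLS): weighted least squares on the
working response, convergence when the relative deviance change falls
below 1e-10 **and** the score, measured relative to the information
scale (`|score_j| / (1 + (|X|ᵀμ)_j)`), falls below 1e-8, with at most
100 iterations.  An absolute score norm is not attainable at arbitrary
data magnitude because the score's floating-point noise scales with
XᵀWX.  The covariance is the inverse Fisher information at the
optimum.  Rank deficiency is detected up front by pivoted QR and
reported with the aliased column's name.  Coefficients larger than 10
in absolute value (rate ratios beyond e¹⁰) are reported as drift flags
— the aggregated-data analogue of perfect separation, typically an
indicator whose cells contain no events; requesting a percent change
for a drifted variable is refused.  A quasi-Poisson dispersion option
(Pearson χ²/df scaling of the covariance) exists but is off by
default, matching the plain-Poisson reporting convention.

Effects are reported as percent change per a stated increment, default
5 µg/m³: `(exp(5β̂) − 1)·100`, Wald 95% bounds transformed identically.
Output headers always state the increment.

## Health impact assessment

`AF = 1 − exp(−βΔ)` with `β = ln(RR)/increment` and `Δ = exposure −
AQG`, clamped to 0 for exposures at or below the guideline: the
counterfactual is guideline compliance, so only preventable deaths are
counted and negative attribution is excluded by design.  The package
ships the meta-analytic PM2.5 relative risks per 10 µg/m³ (1.08
non-accidental, 1.11 cardiovascular, 1.10 respiratory, 1.12 lung
cancer) and the 2021 AQG values; NO2 entries are configurable
user-supplied defaults, not literature constants, because no published
NO2 risk set accompanies the design being emulated.  Attributable
deaths default to the tract-resolved form `AD = Σ_t TD_t·AF(x_t)/years`
with an aggregate citywide-mean mode (population-weighted mean
exposure applied to citywide totals) for diagnostics; the two agree
exactly when exposure is spatially constant.  Uncertainty substitutes
the RR bounds; a seeded lognormal Monte-Carlo mode is a possible
extension but deterministic bound substitution is the default.

On the calibrated preset the citywide-mean PM2.5/natural figure lands
near 108 deaths/year.  This sits inside the plausibility band
[60, 130] used by the validation tests; the band is deliberately wide
because the emulated study's published total is not reconstructible
from its printed margins (see Limitations).

## Synthetic city generator

The generator is the study-condition definition, not a convenience
fixture.

* **Geometry.** Seeded Voronoi tessellation of uniform random points
  clipped to a square 123 km² extent (irregular polygons exercise the
  clipping code); a rectangular `grid_tracts` mode provides exact
  geometry for tests.  Rings are canonicalised (CCW, lexicographically
  smallest start vertex) so identical seeds give identical vertex
  lists.
* **Population.** 100,343 residents; tracts whose centroid lies within
  800 m of the harbour centroid receive exactly the 10,258-person
  harbour share (largest-remainder apportionment by area within each
  stratum), emulating the denser city centre.  Within tracts, the 10
  age-sex strata are drawn multinomially from the published margins;
  age and sex are treated as independent because no joint distribution
  is published.  Deprivation is sampled per tract from the six-category
  distribution (including an explicit missing level), independent of
  exposure.
* **Exposure surfaces.** `background + amplitude·exp(−d/1500 m) +
  smooth noise` on a 60 × 60 grid of 500 m cells (a 30 × 30 km
  domain).  The noise is Gaussian-filtered white noise (correlation
  length 1.5 km) scaled to the observed between-tract SDs (4.7 PM2.5,
  6.3 NO2); without it, regression standard errors would be an order
  of magnitude larger than the emulated study's.  Calibration matches
  the harbour/rest population-weighted tract means exactly: amplitude
  by bisection on the monotone harbour-rest gap of the unit decay
  field, background analytically, and the realised noise recentred by
  projecting out its {1, decay} component so the stratum contrast is
  carried by the deterministic term.  Pollutants draw independent
  noise streams.
* **Deaths.** Cause- and age-specific baseline rates (per person-year)
  follow a plausible schedule rising steeply with age, with a 1.25
  male rate factor; each cause's level is rescaled so the *expected*
  5-year totals equal the published margins exactly, so simulated
  totals differ only by Poisson noise.  True exposure effects, per
  5 µg/m³ PM2.5: natural +2.5%, cardiovascular +6.5% (the recovery
  truth), lung cancer +15.3%, respiratory and all-cancer null.
  Deprivation log rate ratios run from +0.10 (most deprived) to −0.06.
  Cardiovascular, respiratory, cancer and a residual component are
  independent Poissons whose means sum to the natural mean, so natural
  = their sum is Poisson with the intended mean and the cause
  hierarchy (sub-causes ≤ natural, lung ≤ cancer, the latter a
  binomial thinning) holds cell by cell; configurations whose effects
  would force a negative residual mean are rejected.
* **Seeding.** A single master seed; every stage (tracts, SES,
  population, surfaces, deaths) draws from its own labelled stream, so
  identical configs give byte-identical outputs.

What the generator does **not** emulate: spatial autocorrelation of
mortality beyond what exposure induces, correlation of deprivation
with exposure (so the preset has no genuine confounding — adjustment
levels 1–3 should and do agree up to noise), migration or population
change over the window, and the fine structure of real dispersion
fields.  Passing tests therefore demonstrate the correctness of the
machinery under the stated data-generating process, not robustness to
confounding structures the generator does not contain.

## Validation experiments

With the city (geometry, exposure, design matrix) held fixed, death
counts are redrawn and the fully adjusted cardiovascular–PM2.5 model
refitted: 1000 replicates for the effect-recovery mean and CI
coverage, 500 for the null type-I error.  1000 replicates put the
Monte-Carlo error of the recovered mean near 0.12 pp, comfortably
inside the ±0.5 pp recovery band; the small upward curvature of the
percent-change transform (≈ +0.07 pp at this SE) is visible but
immaterial.  Replicate totals and death-weighted exposures were
checked against their analytic expectations, and fitting the model to
the exact expected counts returns the true 6.5% to machine precision,
confirming the model family contains the generator's truth.

## Determinism and I/O

All writers are atomic (`.partial` then rename) and format floats
explicitly, so rerunning the pipeline with the same config and seed
produces SHA-256-identical text artifacts; the manifest records the
digests.  The pipeline re-reads the grids it writes so a
`--skip simulate` rerun over the same files is bit-identical to the
original run.  ESRI ASCII grids are stored top-row-first on disk and
converted to the internal lower-left convention at the I/O boundary;
grid round trips are exact at the 10-significant-digit write format.
The bar-chart PNG is excluded from digest comparisons (binary,
backend-dependent); its underlying CSV is digested instead.

## Problem sizes

Default experiment sizes — 722 tracts, 60 × 60 grid cells, 1000 + 500
validation replicates — were chosen so the full test suite and the
acceptance script each complete in a few minutes on a single core
while keeping Monte-Carlo error well inside every asserted band.

## Limitations

* The published headline estimates this design echoes (e.g. +7.6% NO2
  cardiovascular, +13.5/24.1/37.9% harbour excesses, 82 + 25
  preventable deaths/year) are not reproducible without the original
  registry and dispersion fields; the crude rate ratio implied by the
  published population margins (≈1.02 for natural mortality) does not
  even match the published crude harbour estimate (+7.2%), so the
  original model's exact specification cannot be recovered.  The
  pipeline therefore validates against properties (closed forms,
  oracles, recovery, conservation) rather than against those numbers,
  and the HIA diagnostic uses a wide plausibility band.
* Membership of a tract in the harbour buffer is by polygon centroid
  (simplest whole-tract rule; an area-overlap ≥ 50% mode and a square
  buffer are provided as sensitivity options since the emulated study
  is ambiguous between a circular-radius and square buffer).
* Wald intervals throughout; no spatial autocorrelation modelling; no
  overdispersion adjustment by default; single-year exposure surface
  taken as the long-term average.
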