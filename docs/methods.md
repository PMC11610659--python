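# Methods

This note documents the models, the synthetic-data generator and the
numerical choices behind `fearscape`, in the spirit of a package methods
appendix: what is assumed, what is simulated, and what passing tests do
and do not demonstrate.

## Coordinate frame, time and the day/night split

All coordinates are planar projected metres on a fictional square grid
(no geographic coordinates anywhere); every distance in the package is
Euclidean. Timestamps are UTC throughout. Day and night are split at
solar elevation 0° computed by a standard low-precision solar ephemeris
(Spencer series for declination and the equation of time) at a fixed
site, default 55.75° N, 6.25° W — a west-of-Scotland location whose
mid-winter days (~7 h) and late-April days (~15 h) span the seasonal
range that matters for activity budgets. No twilight band is modelled:
published analyses split day and night without defining one, and a
single elevation threshold keeps the split reproducible.

Winters are labelled `YYYY-YYYY+1` and span 1 October – 30 April; the
date index counts days since 1 November of the winter (1 Nov = 1, so
2 Jan = 63). Generated tracks span 1 November – 30 April.

## The synthetic landscape

A square extent (default 10 × 10 km) is tiled with rectangular farms on
a jittered grid (default 5 × 5), each split into 2 × 2 fields; a seeded
20% of fields are designated for shooting. The habitat raster (default
20 m cells) carries the seven-class scheme used throughout (improved
grassland, other grassland, arable, saltmarsh/coastal, bog, freshwater,
other); classes are assigned by ranking a smoothed Gaussian noise field
and cutting at the configured proportions, which makes class shares
exact and the map spatially coherent. Roads are a handful of gently
wiggled polylines; roosts sit in the outer ring of the island.

## Movement generator

Each bird owns a roost and a pool of familiar farms near it. Night
fixes sit on the roost with 30 m GPS jitter. By day the bird starts at
its current farm's centroid and takes gamma-distributed steps
(shape 20) in uniformly random directions, tethered to within 600 m of
the centroid by reflecting the radial step component (so realized step
lengths equal the drawn lengths). The step mean is calibrated once per
winter as `daily_target / mean daytime steps per day`, so the
winter-average undisturbed daily distance matches the configured
species target (defaults 3.14 km GBG, 2.38 km GWfG) while individual
days track day length — short mid-winter days yield shorter totals,
a realistic seasonal signal. Birds switch farms with probability 0.1
per day.

## Shooting and the injected displacement response

Events are Poisson per day (default 1/day), placed between 2 h after
sunrise and 2 h before sunset so the steps flanking an event are
ordinary foraging steps, and at least 3 h apart within a day — one
field is not shot over repeatedly, and (important for testing) a bird's
control step never overlaps a previous event's response. Each event
targets the shooting field nearest a randomly chosen bird's current
position, as marksmen shoot where geese are; this concentrates
exposure distances at the low end, as in real logs.

For every bird whose most recent fix (≤ 1 h old) lies within the
exposure radius (default 4000 m, the pair-retention distance), the next
step is rewritten to length

    SL_t = max(0, SL_{t−1} + β₀ + β₁ ln(max(d, 1 m)) + ε),  ε ~ N(0, 70 m)

in a direction away from the event (uniform within ±90° of the
event-to-bird bearing), and the rest of that day's fixes are shifted
with the bird — the flock resettles elsewhere, leaving subsequent step
lengths untouched. The injected *difference* SL_t − SL_{t−1} therefore
follows the signed linear decay law over the whole 1 h / 4 km retention
range: birds beyond the decay root (where β₀ + β₁ ln d = 0; ≈ 2056 m
for the GBG defaults) shorten their steps slightly rather than being
clamped to exactly zero response. This is a deliberate design choice:
it makes the generated data match the fitted model form exactly, so the
displacement fit is an unbiased estimator of the configured (β₀, β₁) —
the generator's core testable property. The only hard floor is physical
non-negativity of the step, which binds with negligible probability at
the default noise SD (70 m, a free parameter; nothing published
constrains it). Event metadata records every perturbed (bird, event)
pair with its distance and realized displacement as ground truth.

Distance to an event is measured from the retained pre-event fix — the
bird's location when exposure begins — consistently in the generator,
the pair builder and the exposure classifier.

## Displacement model and disturbance distance

Step pairs are built exactly by the retention rule (pre-event fix
within 1 h and 4 km; three consecutive fixes; nearest event kept when
several are eligible for one step). The mixed model uses the natural
log of distance (floored at 1 m), a quadratic in event time-of-day
(hours since midnight, uncentred, so the intercept is directly
comparable with published estimates), and either a fixed winter factor
(two-winter species) or a crossed winter random intercept (many-winter
species, fitted via variance components). Estimation is REML through
several optimizers in turn; a candidate is accepted only if it
converged with a finite, positive covariance of sensible scale, and the
final fallback is individual-clustered OLS — the fixed-effect estimand
is identical, only the efficiency differs.

The disturbance distance is the smallest d where the lower 95% CI of
the predicted decay curve (at mean event time, reference winter,
fixed-effect uncertainty only — matching how a single mean regression
band is displayed) reaches zero: a 10 m grid scan refined by bisection
to ±0.01 m, with an infinity sentinel when the lower band stays
positive across the grid or the distance slope is non-negative.
Published crossing distances for the non-target species appear in two
places with two values (644 m and 664 m); the package uses 644 m — the
value used for exposure classification — as the species default, and
reports its own computed crossing alongside.

## Exposure, rates and experience

A goose-day is disturbed if any fix in the half-open hour before an
event ((t−1 h, t]) lies within the species buffer of the event's field
centroid; days split three ways as undisturbed / nearby / in-field
(any qualifying fix inside the shot field polygon, boundary counted as
inside). One fix may count toward several near-simultaneous events.
Rates are exposure events per tracked day per individual-winter, with
per-species means and standard errors across those rows. Cumulative
experience is the running count of disturbed days within an
individual-winter, z-scored globally before modelling ("scaled" being
otherwise unspecified, a global z-score keeps coefficients comparable
across model sets).

## Daily distance, budgets and ODBA: estimation backend

The published analyses fit gamma and beta-binomial GLMMs with AR1
covariance in specialized mixed-model software. Here the estimand — the
fixed-effect structure — is recovered with a documented two-stage
scheme for the gamma models: a gamma GLM (log link) supplies
coefficients and the AIC used for model ranking; a GEE refit with an
AR1 working correlation over each individual-winter day series
(correlation ρ^Δdays, so gap days decay the dependence) supplies
autocorrelation-robust covariance and the ρ estimate, with
cluster-robust GLM covariance as fallback. Marginal means are
back-transformed at scaled experience 0 and the reference sex, with
delta-method CIs on the log scale. Recovery tests verify the scheme:
injected marginal means (3.14/4.32 km), null effects, and latent AR1
(ρ = 0.5 recovered within [0.3, 0.7] at n = 2000) are all reproduced,
and on serially independent data the AR1 refit moves no coefficient by
more than one standard error.

The beta-binomial model is an exact maximum-likelihood regression
authored in-package (logit link; a = θπ, b = θ(1−π); log-likelihood via
log-beta functions; BFGS with numerical Hessian). It carries fixed
effects only: the between-bird and between-winter heterogeneity that a
random intercept would absorb loads onto the dispersion parameter θ
instead. That costs some efficiency but leaves the Shot/Night contrasts
— the quantities of interest — unbiased, as the null-coverage tests
check. The three-model budget set (global, minus interaction, minus
Shot) and the five-model ODBA set are ranked by AIC with failed fits
recorded and excluded.

ODBA is computed exactly as the per-burst sum over axes of mean
absolute deviations; daily totals sum daytime bursts. Inclusion rules:
≥ 6 bursts per goose-day/-night, ≥ 10 days per individual-winter,
≥ 8 fixes per goose-day for distances. Goose-nights attach to the date
of the preceding sunset (bursts before local noon belong to the prior
evening's night) and inherit that day's disturbance flag, since
shooting is diurnal.

## Behaviour classification

The classifier is a random forest (200 trees) over per-axis mean, SD,
min, max and mean absolute deviation, plus ODBA and the dominant-axis
ratio — a standard moment-feature set for accelerometer ethograms.
Training uses a stratified 70/30 split at fixed seed; accuracy is
reported with a Clopper–Pearson CI and a five-class confusion matrix,
after which alert and resting collapse to "stationary" for analysis.
The synthetic training set defaults to the published per-class counts
(walking 376, grazing 1689, alert 472, resting 287, flying 1753) with
class-distinct static postures and a dynamic-noise ordering
resting < alert < grazing < walking < flying; the classes are cleanly
separable by design, so held-out accuracy at or near 1.0 demonstrates
the pipeline (features → split → forest → evaluation), not classifier
performance on real, messier signals.

## Habitat selection

Availability is the 100% convex hull of a species' daytime fixes;
pseudoabsences are uniform inside it by seeded rejection sampling at
exactly 10 per used fix, generated once per species and shared across
classification levels (classification variables are assigned by
replication; within-day tables take a seeded 10:1 subsample split over
periods). Weighted logistic GLMs (10 used / 1 pseudoabsence, no random
intercepts — the used:pseudoabsence ratio is constant by design) fit
habitat × shooting-day between days and habitat × period ×
scaled-road-distance within disturbed days, where the period splits at
the first exposing event's timestamp and habitats with fewer than 50
used fixes in both periods collapse to "other". Road distance is
z-scored over the table being fitted. Evaluation: ROC/AUC on the
predicted scores plus a confusion matrix at probability 0.5 on the
weighted score (no published threshold exists; 0.5 is the natural
midpoint of the weighted design).

## Recovery studies and their scale

`fearscape.validation` runs the three headline recovery studies at a
fixed, deliberately modest scale chosen to finish in seconds on one
CPU while keeping each estimator informative about its target effect:

* displacement: 30 birds per species, one winter, ~230 events
  (~2000–2500 retained pairs per species) — intercept SE ≈ 50 m,
  slope SE ≈ 3 m per log-metre;
* daily distance: 13 birds per species × 120 days (~3100 goose-days),
  day-level gamma shape 16 (CV ≈ 0.25, appropriate for route-faithful
  commuting geese), between-individual log-scale SD 0.12 with unit-mean
  correction so population-averaged means equal the configured truth
  exactly, disturbance probability 0.2/day, latent AR1 ρ = 0.4 — the
  disturbed−undisturbed difference is estimated to ≈ ±0.08 km, which
  is what makes a ~1.2 km effect a meaningful recovery target;
* classifier: the published class counts, 70/30 split.

## What the synthetic tests do not show

The generator emulates structure, not nature: circular farm tethering
rather than field-boundary foraging; behaviour drawn independently per
burst from a day/night schedule (no behavioural response to shooting is
injected, so budget models on full synthetic runs correctly find no
Shot effect); Gaussian burst noise without the autocorrelated,
gravity-rotated signal of real accelerometers; no weather, tides,
tag duty-cycle gaps or GPS error beyond roost jitter. Passing recovery
tests therefore demonstrates that the estimators are correct for data
with the assumed structure — they do not validate the biological
conclusions on real tracking data, which remain restricted.

## Known limitations

* The two-stage gamma scheme and the fixed-effect beta-binomial are
  population-averaged approximations to the fully crossed random-effect
  fits; variance components for winter and modal farm are not reported.
* AIC ranking uses the independence likelihood (stage 1); with strong
  autocorrelation the ranking is conservative about interaction terms.
* The within-day RSF assigns pseudoabsence periods by alternation
  rather than by per-point availability in time.
* Confusion-matrix metrics depend on the 0.5 threshold convention and
  on the weighted score scale; AUC is threshold-free and should be
  preferred for comparisons.
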