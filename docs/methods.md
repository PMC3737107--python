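# Methods

This note documents the statistical model behind `nestsurvey`, the choices
made where the methodology is genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## The nest-census model

Weaned chimpanzees ("nest builders") construct roughly `p` nests per
individual per day; a nest remains detectable for a mean of `r` days.  At
stationarity the standing nest density therefore satisfies

    D_nest = D_builder · p · r.

Two census designs sample this process:

* **SCNC (standing-crop nest count)** counts all nests seen on a single
  pass of each line transect.  With `n` detections after truncation at
  `w`, and `f(0)` the fitted probability density of perpendicular
  detection distances at zero, nest density is the conventional
  line-transect estimator `D̂_nest = n·f̂(0)/(2L)`.  Converting to builders
  requires `p` and `r`.
* **MNC (marked nest count)** revisits transects at short intervals and
  counts only nests built since the previous visit inside a strip of
  half-width `s` where detection is near certain; builder density is
  `D̂_builder = n_new/(2·s·L·t·p)` with `t` the days spanned by the visits.
  MNC needs no decay rate, so an SCNC/MNC pair from the same survey lets
  one back-solve `r = D̂_nest/(D̂_builder·p)`.

CVs of products and quotients of independent estimates combine by the
first-order delta method, `cv_total = sqrt(Σ cv_i²)`.

## Detection functions

Key-plus-adjustment series in the conventional distance-sampling family:

    g(y) = key(y) · [1 + Σ_{j=1..m} a_j cos(jπy/w)],   0 ≤ y ≤ w,

with `key` uniform or half-normal `exp(−y²/2σ²)`.  The likelihood is the
truncated density `f(y) = g(y)/∫₀ʷ g`; the normalizing integral uses
128-node Gauss–Legendre quadrature (machine precision for these smooth
integrands; the unit-integral property is asserted to 1e-6 in tests with
an independent adaptive rule).

Numerical choices:

* **Optimizer** — bounded L-BFGS-B from 5 jittered starts (deterministic
  given the fit seed, default 0), convergence 1e-8 on the objective.
* **Shape constraints** — `g` must be nonnegative and non-increasing (a
  detection "shoulder") on a 512-point grid.  The objective carries a
  linear-plus-quadratic hinge penalty with no slack, which keeps the
  optimizer strictly inside the feasible region; feasibility at tolerance
  1e-6 per grid step is re-checked on the returned optimum and infeasible
  candidates are rejected.
* **Sample-size floor** — the cosine order is refused when `n < 5·(1+m)`;
  bare key functions are allowed down to very small `n` so that sparse
  habitat strata remain fittable.
* **Model selection** — minimum AIC; ties break toward fewer parameters;
  a forward-stepwise search adds cosine terms while AIC decreases
  (maximum order 3).  Selection is invariant to candidate order.
* **Truncation** — fixed `w`, or discard of the largest `⌈fraction·n⌉`
  distances (5% is the conventional omnibus choice), with the discard
  tally retained.
* **Goodness of fit** — χ² on equal-width bins (default
  `min(10, ⌊n/5⌋)`, df = bins − 1 − parameters, error if any expected
  count < 1), KS and Cramér–von Mises against the fitted CDF.  P-values
  are naive in the usual way: parameters are treated as known, as standard
  distance-sampling software reports them, which makes the tests mildly
  conservative.  No parametric-bootstrap correction is applied by default.
* **Strip half-width** — `s = max{x : g(x)/g(0) ≥ τ}` with τ = 0.9 by
  default.  No operational rule for "the extent of the shoulder" is
  standard; τ is configurable.  For a flat detection function `s = w`.

Detection functions may be fitted pooled or per habitat (default
per-habitat in the pipelines).  When a sparse stratum cannot support its
own fit the pipeline falls back to the pooled fit for that stratum and
logs it.

## Density pipelines and uncertainty

Lengths are stored in km, distances in m, densities per km²; the single
m↔km conversion lives in `units.py`.

The bootstrap resamples **transects** with replacement — the transect is
the replicate sampling unit of a systematic line-transect design — with
`B = 999` resamples by default, percentile 2.5/97.5 intervals, and
`cv = sd/mean` of the bootstrap distribution.  Detection (`f(0)` or `s`)
is held fixed across resamples, so intervals reflect between-transect
encounter-rate variance; this is cheaper and slightly anti-conservative
relative to refitting the detection function per resample, and is the
analogue of treating detection parameters as known in the CV chain.
Degenerate data (all transects identical) give a zero-width interval.
Failed resamples are dropped; more than 20% failures aborts.

Global densities are area-weighted means of habitat-specific estimates,
`D = Σ A_h D_h / Σ A_h`.  Habitat areas are an explicit user input: the
per-habitat transect composition determines *effort*, not park-level
habitat area, and the two weightings differ in general.  When no areas are
supplied the pipelines fall back to effort weights.

Builder densities converted from SCNC nest densities copy the nest-density
CV and relative CI by default, treating `r` and `p` as constants; full
delta-method propagation (with a lognormal interval rebuilt from the
combined CV) is available behind `propagate_rate_cvs=True`.

## Spatial randomization test

Nests, features (roads, rivers, settlements) and transects live in one
planar projected coordinate system in metres; inputs whose coordinates all
fit in the lon/lat box are rejected as likely unprojected (the guard can
be disabled for deliberately small toy geometries).  Duplicate nest
coordinates — several nests in one tree sharing a GPS reading — are
collapsed to unique locations before testing.

The surveyed region is the union of flat-capped buffers of half-width
84 m (the maximum observed nest distance) around the transects; overlaps
are merged so uniform sampling never double-weights shared area.  Random
points are drawn by rejection from the bounding box.  The observed
statistic is the mean nearest straight-line distance from nests to the
feature layer; the null distribution is that mean over `R = 1000`
relocations of the same number of uniform points.  The one-sided p is the
fraction of null means *below* the observed mean (near 1 ⇒ nests farther
from the feature than chance, near 0 ⇒ nearer); because that sign
convention reads awkwardly for attraction, a two-sided companion
(`2·min(tail, 1−tail)`) and the standardized `Z = (obs − mean)/sd` of the
null are always reported.  With a degenerate null (`sd = 0`) Z is NaN.

## The synthetic survey generator

Defaults encode the study regime the estimators target: 11 north-south
transects of 3 km on a 5×6 km grid; habitat mosaic with proportions
dense forest 0.2628, open forest 0.0997, savannah-woodland 0.4681 and a
pooled remainder 0.1694, drawn i.i.d. over 100 m segments; builder density
0.5/km² (uniform over habitats by default); production 1.143
nests/builder/day; exponential nest lifetimes with mean 294 days;
half-normal detection with σ = 10/18/25/25 m for DF/OF/SAV/other (nest
distances are shortest under dense canopy); a simulation band of ±84 m;
and biweekly visits, 4 in year one and 5 in year two.  Roads, rivers and
settlements are placed with a configurable bias toward open-habitat
segments, mimicking the association of human infrastructure with low
canopy cover.

Births are a Poisson process with intensity `D_builder·p` per km² per day
in the band.  The process starts three mean lifetimes before the first
visit **from an exact stationary cohort**: the initial standing crop is
Poisson with mean `D·p·r` per unit area, with exponential ages and
residual lifetimes (valid by memorylessness).  The standing crop is
therefore exactly stationary at every visit; the burn-in window only
provides the birth history needed for marking logic.

First visits emit the standing crop (SCNC stream); later visits emit only
nests born since the previous visit (`is_new = 1`, MNC stream), each
detected with probability `exp(−x²/2σ_h²)`.  A marked nest is never
re-emitted.  The MNC assumption that no new nest disappears between
visits is deliberately violated at the natural rate ≈ interval/(2·mean
lifetime) ≈ 2.4%; it is part of what the recovery experiment absorbs.
All randomness flows from the single config seed through fixed per-stage
substreams, so identical config+seed reproduces a survey bit-for-bit.

What the simulator does **not** emulate: nest-group (party) clustering,
habitat- or season-dependent decay, observer heterogeneity, and measurement
error in distances.  Passing recovery tests therefore demonstrate internal
consistency of the estimation chain under the stated model, not robustness
to those field realities.

## Experiment design and problem sizes

The validation experiments (shared by the test suite and
`scripts/acceptance.py`) use: 200 replicates for standing-crop
stationarity (±3% check on the mean against 168 nests/km²); 100 replicates
for the MNC → decay → SCNC recovery chain (medians within ±20% for builder
density and ±15% for decay; observed ≈ −4% and −1% at seed 1); 200
experiments of R = 199 for null calibration of the randomization test
(rejection rate 5% ± 4%); and 500 surveys × B = 999 for bootstrap
coverage.  These sizes give Monte Carlo standard errors comfortably below
each check's tolerance.  The recovery chain runs SCNC pooled (the pooled
2010 stream is ample, and a pooled flexible fit is consistent for the
aggregate density) and MNC per habitat, because a pooled strip width badly
violates the near-certain-detection assumption inside dense forest.

## Known limitations

* The 95% percentile bootstrap interval genuinely under-covers with only
  11 transects: its true coverage at the default regime is ≈ 90–91%
  (verified against an independent implementation), the familiar small-n
  shortfall of the percentile method (bootstrap sd scales by
  `sqrt((n−1)/n)` and the interval ignores the t-distribution tail).
  Intervals from 11-transect surveys should be read as approximate.
* GOF p-values do not account for estimated parameters (see above).
* The decay model is a single mean lifetime; decay-curve shape, covariates
  and seasonality are out of scope.
* The spatial test assumes the supplied layers are complete and in the
  same projection; no reprojection or datum handling is attempted.
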