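# Methods

This note documents the models implemented in `kelpcanopy`, the defaults
and their rationale, what the synthetic data does and does not emulate, and
the choices made where the methodology is genuinely open.

## Scope and data model

The package processes six-band surface-reflectance scenes (blue, green,
red, NIR, SWIR1, SWIR2; unitless reflectance in [0, 1]) on a north-up
projected grid with pixel-centre georeferencing, each with a QA code
raster and acquisition metadata (date, sensor generation, tide height).
Classification uses all six bands; spectral unmixing uses only the first
four, where kelp/seawater contrast lives.  Cell polygons are axis-aligned
rectangles in projected metres; pixel membership is by pixel centre in the
half-open rectangle [x0, x1) × [y0, y1), which tiles a grid without double
counting.

## Masking

* **Clouds**: a pixel is masked iff its QA code is in the configured cloud
  dialect (default: code 1 = cloud).  QA conventions differ between product
  collections, so the dialect is a parameter; unknown codes pass through
  unmasked and are logged.
* **Land**: elevation strictly greater than 0 m.  Missing elevations are
  masked (a coastal pixel without elevation cannot be trusted to be water).
* **Intertidal**: from a single cloud-free reference scene acquired at
  negative low tide, pixels with MNDWI strictly below 0.1 are masked.
  MNDWI = (green − SWIR1)/(green + SWIR1), undefined where the denominator
  is zero.
* **Tidal flagging**: among pixels within 1 pixel (8-connectivity) of land,
  a pixel with ≥ 8 paired observations is flagged when the OLS slope of
  canopy area against tide height is negative with two-sided p < 0.05.
  "Adjacent", the minimum n, and α are not prescribed by the underlying
  methodology; these defaults are package choices.  Flagged pixels are
  reported, not removed — removal is an opt-in switch, since in operational
  use the flags feed a manual review.

## Classification

Brightness normalization divides each spectrum by its six-band mean; the
operational product's normalization is not published, and this choice is
the simplest one that is scale-invariant (sun glint, haze, exposure).
Training spectra are grouped by k-means (k = 15, Euclidean distance, 10
seeded restarts keeping best inertia) and each cluster is assigned one of
the four classes — by an explicit mapping (the analyst route) or by
majority ground-truth class (the automated route used in tests and in the
synthetic pipeline).  The classifier is a CART decision tree (Gini
impurity, axis-aligned splits, default max depth 8, no pruning), one per
sensor generation (TM/ETM+ vs OLI) with no parameter sharing.  In the
synthetic pipeline the training set samples 12 scenes spread across each
generation's time span (8,000 pixels) so that per-scene seawater
variability is represented; trees serialize to portable JSON and predict
identically after a round trip.

Intertidal pixels are excluded from classifier training: they alternate
between land-like and water-like with the tide and are handled by the
intertidal mask instead.

## MESMA unmixing

Two-endmember, sum-to-one linear mixing with no shade endmember: for pixel
spectrum `x` and candidates kelp `K` (one static spectrum) and seawater
`W_i` (30 per scene), the least-squares fraction has the closed form
`f* = Σ_b (x_b − W_b)(K_b − W_b) / Σ_b (K_b − W_b)²`, clamped to [0, 1]
*before* RMSE evaluation so the reported model is a feasible proportion.
The candidate with minimum 4-band RMSE wins; ties break to the lowest
index for determinism; candidates with `W = K` are skipped.  Seawater
endmembers are a seeded, spatially stratified sample of seawater-class
pixels (round-robin over a 5×6 stratum grid) — the operational selection
procedure is unpublished, and stratification guarantees distinct water
masses are represented.  Fractions are computed only for kelp-class
pixels; other unmasked pixels get 0, masked pixels are missing.  Canopy
area is fraction × pixel area (900 m² for 30 m pixels).

Property tests verify: exact recovery (≤ 1e−6) of noiseless mixtures over
the full fraction range; equality with a 1e−4-step brute-force grid search;
monotonicity in the true fraction; and a mean absolute fraction error
< 0.05 under 0.01 per-band noise.

## Aggregation rules

All rules use strict inequalities, checked on both sides by tests:

* cell-quarter missing iff the unobserved share of the cell's habitat
  pixels **exceeds** 25% (exactly 25% is kept).  The denominator is the
  cell's habitat pixels by default and is configurable to all water pixels
  — which population of pixels the 25% refers to is ambiguous in the
  source methodology.
* cell-year missing iff **two or more** quarters are missing; otherwise the
  annual value is the max over non-missing quarters.
* region-year missing iff **more than half** of the region's cells were
  missing more than one quarter.  In non-missing years, sporadically
  missing cells contribute 0 with a logged warning by default; strict
  NaN propagation is available (`strict_missing`) — the source methodology
  does not state which behaviour was used, so both are implemented and
  neither is asserted as canonical.
* cells with **fewer than** 500 (10 km scale) or 25 (1 km scale) habitat
  pixels are excluded.  A habitat pixel is one where canopy was detected at
  least once across the series.
* quarters are calendar quarters (Jan–Mar, …, Oct–Dec).
* per-pixel seasonal statistics: mean over cloud-free acquisitions, SE =
  sample sd/√n (0 when n = 1), overpass count; a pixel with no cloud-free
  acquisition is missing.

## Trend model

Annual series are normalized by their maximum, so slopes read as percent
of maximum per year.  The model is `y_t = β₀ + β₁·year_t + ε_t` with ε an
AR(p) process, p ∈ {0, 1, 2}.  The exact Gaussian likelihood is evaluated
through the stationary autocorrelation at the observed year lags
(ρ(h) = φ^h for AR(1); the Yule–Walker recursion for AR(2)), which handles
missing years without interpolation.  AR coefficients are parameterized by
partial autocorrelations through the Levinson–Durbin recursion, so every
candidate in the search space is stationary; fits that end on the
stationarity boundary (|pacf| > 0.998) are marked invalid and excluded
from selection.  AIC = 2k − 2 lnL with k = 3 + p (intercept, slope,
innovation variance, AR coefficients); the minimal-AIC order is reported.

**Estimation and inference choices.**  The default likelihood is REML
(`method="reml"`), as in the `nlme` machinery this analysis style comes
from; with the mean model fixed, restricted likelihoods are comparable
across AR orders, so REML-AIC selection is valid.  For the slope
covariance, the fitted AR coefficients receive the standard small-sample
bias correction (each partial autocorrelation π → π + (1 + 3π)/n), which
counters the well-known downward bias of estimated autocorrelation in
short series; the reported coefficients remain the uncorrected estimates.
The residual variance uses denominator n − 2, so the AR(0) fit reproduces
ordinary least squares exactly; p-values are two-sided t with n − 2 − p
degrees of freedom.  Plain ML (`method="ml"`, no correction) is retained
and is cross-checked in the tests against the exact state-space likelihood
of `statsmodels.SARIMAX`.

This combination was chosen by measuring calibration on ~40-year series:
Monte-Carlo experiments in the test suite show a type-I error rate of
~0.05 on 1,000 null white-noise series and 95%-CI coverage of ~0.92 on 500
AR(1) (φ = 0.5) series with a 0.8 %/yr trend, where ML plug-in inference
under AIC selection is noticeably anticonservative.  A perfectly fit line
(zero residual) is handled by a variance floor (1e−12) so that order 0 is
selected rather than a boundary AR fit.

## Heatwave metrics

Relative to the 1984–2013 baseline mean of annual canopy:
response = 100 × min(2014–2016); recovery = 100 × mean(2017–2021);
recent state (local scale) = 100 × mean(2014–2021).  Missing years are
dropped from both numerator windows and the baseline; a zero baseline mean
raises an error (the percentage is undefined).  Values above 100% are
legitimate (post-event canopy larger than the historical mean).  All three
are invariant to rescaling the series.  Latitude gradients use Pearson
correlation of log(% + 1) against cell-centroid latitude, two-sided p via
t with n − 2 df; the +1% offset keeps zero-canopy cells finite, and
degenerate (zero-variance) inputs return a flagged invalid result.

## Synthetic data: what it emulates, what it does not

The generator produces the study conditions used by every end-to-end test:
a 38-year archive starting 1984, 4 calendar quarters per year with 3
acquisitions per quarter, a 2×2 grid of cells (24×24 pixels of 30 m) with
a land strip, an intertidal fringe at elevation exactly 0 m, 4 discrete
seawater "water masses", one kelp patch per cell, random cloud blobs
(expected coverage 15%, optionally fully clouded quarters), per-band
Gaussian reflectance noise (default 0.005 in the pipeline), and sinusoidal
tides.

The true annual canopy level follows trend + decadal oscillation (period
10 yr, amplitude 0.1) + multiplicative AR(1) noise (innovation sd 0.05,
φ = 0.3) — multiplicative because interannual variability scales with
abundance and canopy cannot go negative — with heatwave years (2014–2016)
forced to `heatwave_depth` (default 0.2) of the pre-event deterministic
baseline mean and 2017–2021 to `recovery_level` (default 0.8), so the
configured response/recovery are exactly recoverable from the noise-free
trajectory.  Within a patch, the level scales *extent*: pixels are
occupied from the patch core outward under a fixed density taper (core
0.6, edge 0.4×core), with the last occupied pixel taking the fractional
residual so that true summed area is exactly proportional to the level
until the patch saturates.  This mirrors how observed canopy loss
manifests (patches shrink and disappear; surviving canopy keeps its
density) and keeps kelp pixels spectrally detectable in all epochs; a
uniform-density alternative makes whole patches flicker below the
classifier's detection limit in collapse years, which is an artefact of
that stand-in rather than of the method.

Seawater varies between scenes (spectra redrawn per acquisition) and
within scenes as discrete water masses rather than continuously — a
deliberate simplification that makes "noiseless scenes unmix exactly with
endmembers sampled from the scene" a meaningful invariant.  The spectra
themselves are qualitative stand-ins (kelp bright in NIR, seawater dark,
land with negative MNDWI, bright flat cloud); no radiometric realism is
claimed.  Consequently, passing tests demonstrate the correctness and
calibration of the *processing chain* under known truth — not the
radiometric accuracy of canopy retrievals from real imagery, which depends
on endmember quality, atmospheric correction and sensor calibration that
the simulator does not model.  Orbital geometry, reprojection, and tide
prediction are likewise out of scope (tide heights are an input).

## Numerical conventions

Seeds: every stochastic component derives from a single configuration seed
via `numpy.random.SeedSequence`; identical configurations give
byte-identical CSV outputs.  Ties in k-means are handled by sklearn's
seeded restarts; ties in MESMA RMSE break to the lowest candidate index;
patch occupancy ordering breaks distance ties lexicographically by pixel
coordinates.  Degenerate inputs (all-zero spectra, single-class training
sets, empty regions, all-degenerate endmember pairs, zero baselines)
raise errors rather than returning silent defaults.

## Problem sizes

The default archive (456 scenes of 48×48 pixels, 4 cells, 38 years) runs
the full chain in a few seconds; the Monte-Carlo calibration experiments
(1,000 + 500 trend fits at n = 38, plus 200 fits at n = 200) dominate the
test-suite runtime at roughly two minutes.  These sizes were chosen to
make the statistical checks sharp while keeping a full verification run
comfortable on a laptop.

## Known limitations

* The heatwave dip is part of the fitted 38-year series, so the fitted
  linear trend is steeper than the configured pre-event trend; the
  AR-inflated standard error absorbs this (the end-to-end check is
  "within 2 SE"), but the point estimate should not be read as the
  pre-event trend.
* CI coverage under AIC order selection is ~0.92, not exactly 0.95:
  conditioning on a selected model is inherently slightly anticonservative,
  and series where order 0 is (wrongly) selected carry OLS-width intervals.
* The classifier's detection limit means very dilute canopy (fraction
  ≲ 0.05 at realistic noise) is partly missed; in the simulator this is
  mitigated by the extent-scaling dynamics, and in real products it is the
  documented submerged/dilute-canopy blind spot of the method.
* `latitude_correlation` on the demo domain's 4 cells is computed but has
  no power; it becomes meaningful on larger grids.
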