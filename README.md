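# kelpcanopy

Satellite monitoring of floating kelp canopy (giant kelp *Macrocystis
pyrifera*, bull kelp *Nereocystis luetkeana*) as a tested, reusable Python
pipeline.  The package implements the full processing chain used to turn
multidecadal Landsat-class surface-reflectance archives into canopy-area
time series and disturbance statistics — and ships a synthetic-scene
generator with known ground truth so every stage is verifiable without
downloading a single satellite image.

Who it is for: remote-sensing ecologists and kelp-forest managers who want
the canopy-area methodology as inspectable, seedable code, and method
developers who need a ground-truthed testbed for masking, unmixing and
trend-detection choices.

## The method

1. **Masking.** Clouds from the per-pixel QA band; land where DEM elevation
   is strictly > 0 m; an intertidal fringe where the water index
   MNDWI = (green − SWIR)/(green + SWIR) of a negative-low-tide reference
   scene is < 0.1.  Pixels whose apparent canopy co-varies negatively and
   significantly with tide height are flagged for review.
2. **Classification.** Spectra are brightness-normalized (divided by their
   six-band mean) and classified into {kelp canopy, seawater, cloud, land}
   by a CART decision tree per sensor generation, trained on k-means-grouped
   (k = 15) labelled spectra.
3. **MESMA unmixing.** Each kelp-class pixel `x` (blue, green, red, NIR) is
   modelled as `x = f·K + (1−f)·W` against the single static kelp endmember
   `K` and each of 30 per-scene seawater endmembers `W`; the closed-form
   least-squares `f* = Σ(x−W)(K−W)/Σ(K−W)²`, clamped to [0, 1], is kept for
   the candidate with minimum RMSE.  Canopy area = `f × 900 m²`.
4. **Aggregation.** Per-pixel quarterly mean/SE/overpass count; grid-cell
   sums with the missing-data rules (cell-quarter missing when > 25% of its
   habitat pixels had no cloud-free look; cell-year missing with ≥ 2 missing
   quarters; region-year missing when > half the cells are missing); annual
   maxima; habitat thresholds of 500 (10 km cells) or 25 (1 km cells)
   pixels.
5. **Statistics.** Max-normalized annual series are fitted with
   `y = β₀ + β₁·year + ε`, ε an AR(p) process (p ∈ {0,1,2}) estimated by
   exact gap-aware (restricted) maximum likelihood, order chosen by AIC;
   slopes are reported in % of maximum per year.  Marine-heatwave response
   = 100 × min(2014–2016)/mean(1984–2013), recovery = 100 ×
   mean(2017–2021)/mean(1984–2013); latitudinal gradients via Pearson r of
   log(% + 1).

See `docs/methods.md` for assumptions, parameter defaults, and the design
choices made where the methodology is under-specified.

## Worked example

Run the full chain on the default synthetic 38-year archive (4 grid cells,
quarterly cadence, 3 overpasses per quarter, configured trend −0.8 %/yr,
heatwave depth 20%, recovery 80%, 5% interannual noise):

```bash
kelpcanopy run-all --seed 1 --out-dir demo_run
```

prints the stage audit counts and the regional summary:

```
{
  "n_acquisitions": 456,
  "n_cells_excluded": 0,
  "n_cells_retained": 4,
  "n_habitat_pixels": 617,
  "n_intertidal_pixels": 48,
  "n_kelp_pixel_detections": 145813,
  "n_land_pixels": 144,
  "n_region_years_missing": 0,
  "n_tidal_flagged": 0
}
regional slope -1.09 %/yr (SE 0.66), response 18.4%, recovery 80.9%
```

Reading the numbers: the fitted regional trend (−1.09 %/yr, AR(1) errors)
brackets the configured −0.8 %/yr well within 2 SE — the heatwave dip
steepens the apparent slope, which the AR-inflated SE absorbs.  The
measured heatwave response (18.4% of the pre-event baseline remaining at
the 2014–2016 minimum) and recovery (80.9% of baseline over 2017–2021)
recover the configured 20% / 80% despite clouds, classification and
unmixing noise.  `demo_run/` holds the quarterly/annual/regional CSV
tables, per-cell statistics, tide-sensitivity flags, the cell GeoJSON, and
`run_metadata.json` with the config hash and seed; re-running with the
same seed reproduces every file byte for byte.

Stage-by-stage equivalents: `kelpcanopy simulate|mask|classify|unmix|
aggregate|trends|heatwave` (see `--help`).

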