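# Methods

## The modelling problem

The package targets the common conservation setting of a census of a
rare, flocking farmland bird: a few dozen presence sites with flock
counts inside a large (order 2,000 km²) agricultural study area, plus
raster layers describing the landscape at 30 m resolution. Two models
are fitted to the same habitat predictors:

* an **occurrence model** (SDM): a random-forest classifier contrasting
  presence sites with ~10,000 random pseudo-absence points. Its
  per-pixel score, the *relative index of occurrence* (RIO), is the
  fraction of trees voting "presence" — a relative suitability ranking
  in [0, 1], deliberately not a calibrated probability.
* an **abundance model** (SAM): a random-forest regressor of flock
  counts at the presence sites. Its per-pixel prediction (*relative
  abundance*, RA) is re-calibrated by ordinary least squares of observed
  counts on predictions, `adjusted RA = A·RA + B`, then clipped at zero.

The two surfaces are combined pixel-wise into the **priority protection
index** `PI = (RIO·RA) / max(RIO·RA)`, an index in [0, 1] whose maximum
marks the cell where high occurrence and high abundance coincide.
Because of the normalisation, PI is invariant to positive rescaling of
RA and monotone in the product; if every product is zero the index is
0/0 and the package raises rather than silently returning zeros.

## Predictor stack

Eleven layers, aligned on a single 30 m grid:

| layer | unit | construction |
|---|---|---|
| distance to pool / river / residential / national road / provincial road / expressway / farmland road / ditch | m | exact Euclidean distance transform, centre-to-centre |
| farmland patch area | km² | 4-connected component size × pixel area |
| MNNDVI, MAXNDVI | – | pixel-wise mean / max over the monthly winter NDVI stack |

Conventions fixed for testability: raster origin at the top-left corner
with half-open pixels (a point on a shared edge belongs to the pixel to
the right/below, so containment is a plain `floor`); distances measured
centre-to-centre; NDVI summaries use the available months and a pixel is
nodata only when every month is missing; non-farmland pixels carry
farmland-area 0 (not nodata) so background points stay usable. Patch
connectivity is 4-connected — either convention is defensible for
raster "field" area, but one must be fixed.

## Model settings

* 1,000 trees by default for both ensembles (500 in the recovery
  benchmark, where OOB estimates are already stable at ~1,200 training
  points); all other tree parameters at scikit-learn defaults.
* Balanced class weights `w_c = N / (2·N_c)` counter the presence /
  background imbalance.
* Validation is out-of-bag: each training point is scored only by trees
  whose bootstrap missed it. Occurrence reports the ROC AUC of the OOB
  scores (Mann–Whitney formulation, ties at ½); abundance reports OOB
  RMSE (count units) and R².
* R² is the squared Pearson correlation of observed vs predicted (the
  symmetric observed-vs-predicted agreement measure); `1 − SSE/SST` is
  available as an option.
* Stepwise predictor selection is greedy forward by OOB R² with
  stopping tolerance 1e-3 and ties broken by candidate order. This is a
  transparent, reproducible stand-in for opaque "stepwise" modes of
  commercial packages and is documented as the package's own procedure.
* The train/test split uses `round(0.8·n)` training rows.
* Pseudo-absences are drawn uniformly over distinct valid pixels,
  *without* excluding presence pixels: contamination is possible but
  vanishingly rare at study scale, and exact-n sampling aids testing.
* Partial dependence is the substitution average — the mean model score
  with one variable pinned across its observed range. A variable the
  fitted model does not use yields an exactly flat curve.
* IDW smoothing (power 2, 12 neighbours by default; both exposed) is an
  exact interpolator used for map cosmetics only: the PI arithmetic
  always runs on unsmoothed pixel values, and the normalising maximum is
  taken over unsmoothed products.

## The synthetic study system

`landsim` generates the landscape the models are exercised on. Farmland
is a thresholded smoothed Gaussian field whose threshold is the
empirical quantile, so the realised farmland fraction matches the
configuration exactly; roads, rivers and ditches are 1-pixel random
polylines (roads straighter, rivers wigglier); pools and villages are
random disks; monthly NDVI is smoothed noise lifted on farmland (winter
cereal) with a mild seasonal drift, clipped to [−1, 1]. Defaults mirror
the full study scale — 1,560 × 1,560 pixels of 30 m (≈ 2,190 km²,
76.4 % farmland), five winter months — while tests and benchmarks shrink
the extent and scale feature counts by area. All randomness flows from
one seed through a fixed `SeedSequence` spawning order.

The virtual species responds through *plateau kernels*: a flat preferred
range per predictor with a constant penalty outside, multiplied across
predictors and rescaled to maximum 1 — the range-shaped response a
partial-dependence plot of a habitat model typically shows. Presence
sites are distinct pixels sampled ∝ p; counts are zero-truncated
gamma-mixed Poisson draws with mean λ(x) and variance = dispersion × mean
(dispersion 4 by default: flock sizes are mostly small with occasional
large flocks; nothing distributional is known about the real species'
flock sizes, so the value is a free modelling choice, not an inference).

What the generator does **not** emulate: realistic road-network
topology, crop rotation through the winter, spatially structured
observation effort, detection failure, and correlations between feature
classes (masks are placed independently and may overlap). Passing
recovery tests therefore show that the pipeline recovers a known
plateau-structured response from ideal presence/count data — not that
any real species follows such a response.

## The recovery benchmark

The benchmark scenario (`priorimap.scenarios`) is a 100×100 landscape
with occurrence dominated by one predictor (distance to residential,
260–430 m band, outside penalty 0.002) plus three weak modifiers, and
abundance driven by a *different* pair (distance to pool, MNNDVI). The
kernel penalties were chosen by computing the ideal ranker's ROC AUC
directly from the true p surface (positives ∝ p, background uniform,
ties at ½): the chosen kernels put that ceiling near 0.95, so "strong
signal" is strong by construction, with headroom below the ceiling for
estimation noise. Per replicate the pipeline uses 200 presence sites,
1,000 pseudo-absences and 500 trees; 20 seeded replicates run in about a
minute. Typical results: mean OOB ROC ≈ 0.92, the true driver tops the
importance ranking in essentially every replicate, and the adjusted RA
surface rank-correlates ≈ 0.8 with true λ.

## Numerical and degenerate-input choices

* Exact-n contracts everywhere the underlying description is
  approximate ("approximately 10,000 background points") — exactness is
  testable.
* `fit_adjustment` on constant observations returns slope 0 and the
  constant as intercept (Pearson r is undefined; R² reported as 0);
  zero-variance predictions raise.
* Adjusted RA is clipped at zero — counts cannot be negative, and a
  negative intercept can otherwise push low-RA pixels below zero.
* An IDW query coinciding with a sample point returns that sample's
  value exactly (the `d^−p` weight would be infinite).
* Report artefacts serialise floats to 6 significant digits and contain
  no timestamps, so regeneration is byte-identical.
* GeoTIFF I/O goes through `tifffile` with explicit pixel-scale,
  tiepoint and nodata tags; single-band float32 surfaces round-trip
  bit-exactly.

## Known limitations

* **OOB pessimism under extreme imbalance.** With very few presence
  points (e.g. 94) against 10,000 background points on a small
  landscape, fully grown trees memorise individual presence sites:
  a left-out presence falls into pure-background leaves and scores 0
  out-of-bag, so the OOB ROC can drop far below the model's true ranking
  skill (in-bag and ideal-ranker ROC both ≈ 0.95+ in the same runs).
  OOB ROC should be read as a conservative bound in that regime; the
  recovery benchmark uses a better-balanced design (200 vs 1,000).
* Tree regressors compress the count range; the linear adjustment
  corrects the scale but cannot restore resolution among the rare,
  very large flocks.
* The landscape generator's land-cover classes are placed
  independently, so a pixel can be both farmland and road; distance
  predictors are unaffected, but class areas are not mutually
  exclusive.
* No spatial cross-validation, thresholded range maps, probability
  calibration, or weighted PI variants (socio-economic weighting is
  explicitly out of scope).
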