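# priorimap

Conservation planners usually map *where* a species occurs (a species
distribution model, SDM) or *how many* individuals a place supports (a
species abundance model, SAM) — but rarely both at once, even though the
two patterns often disagree. `priorimap` implements a complete
occurrence + abundance modelling pipeline for raster landscapes with
point observations of flocks, and fuses the two predictions into a single
**priority protection index**:

```
PI = (RIO × RA) / max(RIO × RA)
```

where **RIO** (relative index of occurrence) is the fraction of trees in
a random-forest presence/background classifier that vote "presence" at a
pixel, and **RA** (relative abundance) is the per-pixel prediction of a
random-forest count regressor, linearly re-calibrated against the
observed flock sizes (`adjusted RA = A·RA + B`, OLS, clipped at zero).
PI lies in [0, 1], reaches 1 exactly where high occurrence and high
abundance coincide, and is invariant to positive rescaling of RA.

The package is aimed at spatial ecologists who want a tested, scriptable
version of this workflow: building Euclidean-distance and land-cover
predictor rasters, sampling random pseudo-absences, fitting and
validating the two models out-of-bag (ROC AUC for occurrence, RMSE/R²
for abundance), stepwise predictor selection, partial-dependence curves,
inverse-distance-weighted map smoothing, and GeoTIFF/CSV export. A
first-class synthetic-landscape generator (`priorimap.landsim`) creates
agricultural study systems with a *virtual species* of known,
plateau-shaped habitat preferences, so every stage can be validated
against ground truth.

## Worked example

Simulate a 100×100-pixel (30 m) farmland landscape, fit both models,
and combine them:

```python
import pandas as pd
from priorimap import *
from priorimap.scenarios import demo_landscape_config, demo_response

config = demo_landscape_config(100, 100, seed=1)
landscape = generate_landscape(config)
stack = build_stack(landscape)                    # the 11 predictor layers

response = demo_response()                        # virtual species, known truth
obs = simulate_observations(landscape, response, seed=2, stack=stack)
background = sample_pseudo_absences(landscape.study_mask, 1000, seed=3)

samples = pd.concat(
    [extract_at_points(stack, obs), extract_at_points(stack, background)],
    ignore_index=True,
)
occ = fit_occurrence(samples, n_trees=500, seed=4)
print(f"occurrence OOB ROC: {occ.oob_roc_auc_:.3f}")
print("top occurrence predictors:", [n for n, _ in occ.importances_[:3]])

rio = predict_rio(occ, stack)

presence = extract_at_points(stack, obs)
abund = fit_abundance(presence, list(PREDICTOR_NAMES), n_trees=500, seed=5)
adj = fit_adjustment(presence["count"].to_numpy(), abund.oob_predictions_)
print(f"abundance OOB RMSE: {abund.oob_rmse_:.2f} birds")
print(f"adjustment: A = {adj.A:.2f}, B = {adj.B:.2f}, R^2 = {adj.r_squared:.3f}")

ra_adjusted = apply_adjustment(adj, predict_abundance(abund, stack))
pi = compute_pi(rio, ra_adjusted)
share = (pi.valid_values() > 0.5).mean()
print(f"priority index: max = {pi.valid_values().max():.1f}, "
      f"share of pixels above 0.5 = {share:.3f}")
```

prints

```
occurrence OOB ROC: 0.928
top occurrence predictors: ['dist_residential', 'mnndvi', 'farmland_area']
abundance OOB RMSE: 10.85 birds
adjustment: A = 0.79, B = 3.85, R^2 = 0.295
priority index: max = 1.0, share of pixels above 0.5 = 0.030
```

The OOB ROC of 0.93 says the classifier ranks a random presence above a
random background point 93 % of the time, and the importance ranking
recovers the virtual species' true dominant driver
(`dist_residential`). The adjustment slope below 1 reflects the usual
range compression of tree regressors (extreme counts are pulled toward
the mean); re-calibration stretches the surface back to the observed
count scale. Only 3 % of pixels exceed PI = 0.5 — the index deliberately
concentrates priority on the few cells that score high on *both* axes.

The same pipeline is available from the shell:

```
priorimap simulate     --run-dir run --rows 200 --cols 200 --seed 17
priorimap build-layers --run-dir run --n-absences 10000
priorimap fit-occ      --run-dir run --trees 1000
priorimap predict-rio  --run-dir run
priorimap fit-abund    --run-dir run --trees 1000
priorimap predict-ra   --run-dir run
priorimap prioritize   --run-dir run
priorimap report       --run-dir run
```

which leaves GeoTIFF surfaces under `run/surfaces/` and metrics,
importance rankings, partial-dependence curves and the
occurrence–abundance relation table under `run/report/`.

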