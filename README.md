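# dendromass

Instance-based (k-nearest-neighbor) estimation of individual-tree dry
biomass, benchmarked against the classical Schumacher–Hall allometric model.

## The problem

Quantifying carbon in forests requires the biomass of individual trees, but
direct determination is destructive and expensive, so biomass is predicted
from easily measured tree attributes. The traditional route is allometry:
fit the log-linear Schumacher–Hall model

```
ln(w) = a + b·ln(dbh) + c·ln(ht) + e
```

by ordinary least squares (w = total dry biomass in kg, dbh = diameter at
breast height in cm, ht = total height in m) and back-transform. In
species-rich stands — e.g. mixed-species environmental restoration
plantings — a single power law can be a poor description, and the OLS
residual assumptions (normality, homoscedasticity, independence) are often
strained.

The instance-based alternative predicts a tree's biomass as the
inverse-distance-weighted mean of the biomass of its k nearest trees in
predictor space:

```
ŵ = Σ uᵢ·wᵢ / Σ uᵢ,    uᵢ = 1/dᵢ  or  1/dᵢ²
```

with the distance d taken as Euclidean, squared Euclidean, Manhattan or
Chebyshev on any subset of the six predictors (dbh, mean crown diameter dm,
total height ht, crown-base height hc, apparent density da, basic density
db). The method is evaluated by leave-one-out cross-validation — each tree
is predicted from all the others, never from itself — and configurations
are ranked by R²adj, Syx = √(RSS/(n−k)), AIC, AICc and BIC.

`dendromass` implements both estimators in scikit-learn style
(`KNNBiomassRegressor`, `SchumacherHallRegressor`), the full benchmark grid
(metric × weighting × neighbor count × variable subset × log transform ×
data-set size), the model-selection criteria, the OLS residual diagnostics
(Shapiro–Wilk, White, Durbin–Watson), and a seeded synthetic-forest
generator so every component is testable without field data. It is aimed at
forest biometricians and anyone comparing local (instance-based) with
global (regression) biomass estimators.

## Worked example

Simulate a heterogeneous two-species forest of 180 trees, then compare the
all-variable Chebyshev kNN (1/d weighting, 5 neighbors, z-scored
coordinates) against the Schumacher–Hall fit:

```sh
dendromass simulate --out forest.csv --n 180 --n-species 2 --seed 11
printf 'metric: chebyshev\nk_neighbors: 5\nweighting: inv_d\nstandardize: true\n' > knn.yaml
dendromass compare --input forest.csv --config knn.yaml
```

prints

```
Schumacher-Hall: ln(w) = -1.383306 + 1.035690 ln(dbh) + 1.107997 ln(ht)
  diagnostics: Shapiro-Wilk W=0.979 (p=0.00919); White LM=54.18 (p=1.92e-10); Durbin-Watson=2.248
SH criteria (loo residuals, original scale):
  n=180  k=3 (k_eff=4)
  R2      = 0.6225
  R2adj   = 0.6182
  Syx     = 21.7010
  ...
kNN chebyshev/inv_d/k=5/dbh+dm+ht+hc+da+db/raw:
  R2adj   = 0.7427
  Syx     = 17.8155
  ...
Syx gain over Schumacher-Hall by distance metric:
             euclidean: +30.4 %
   quadratic_euclidean: +33.5 %
             manhattan: +37.1 %
             chebyshev: +17.9 %
```

The fitted allometric coefficients are close to the generator's truth
(a = −1.3908, b = 1.0515, c = 1.0843); on this heterogeneous stand every
kNN variant reduces the standard error of estimate relative to the
allometric model (positive Syx gain), while on data generated exactly from
a log-linear law the allometric model wins — the gain is a measure of how
far the stand departs from a single power law. The same comparison is
available from Python via `dendromass.compare_to_allometry`, and the full
192-cell configuration sweep via `dendromass run-grid --single-dataset`.

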