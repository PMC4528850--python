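# Methods

## Estimators

**Schumacher–Hall allometry.** `SchumacherHallRegressor` fits
ln(w) = a + b·ln(dbh) + c·ln(ht) + e by OLS (statsmodels). Predictions are
back-transformed by plain exponentiation by default; the Baskerville
correction exp(s²/2), with s² = RSS/(n−3) the log-scale residual variance,
is opt-in (`correction="baskerville"`). Plain exponentiation estimates the
conditional *median* of a lognormal response and under-predicts the mean by
the factor exp(s²/2); we keep it as the default because it is the common
field practice the package benchmarks against. Rank deficiency of the
design (e.g. constant diameters) raises with the collinear column named.

**Instance-based kNN.** `KNNBiomassRegressor` predicts a query as the
inverse-distance weighted mean of the k nearest training trees. Distances
are exhaustive (no spatial index): target datasets are a few hundred trees
and the dense n×n matrix is both fastest and exactly reproducible.
Numerical choices:

* **Zero distances.** Weights 1/d and 1/d² diverge at d = 0; the
  prediction degenerates to the unweighted mean of the zero-distance
  neighbors, the limit of the weighting as d → 0.
* **Ties.** Neighbor ties at the k-th boundary break by ascending record
  position (stable argsort), so results are deterministic under any input
  ordering of equal distances.
* **Manhattan.** The `literal_manhattan` switch reproduces a published
  variant in which the Manhattan formula squares the absolute differences
  and therefore duplicates the squared-Euclidean distance; the default is
  the standard city-block sum the name denotes.
* **Scaling.** Features enter in native units by default (dbh in cm
  against densities in g/cm³), matching the benchmark protocol;
  `standardize=True` z-scores coordinates with the training mean and SD.
  See "Feature scaling" below — the choice is consequential.

**Leave-one-out cross-validation.** `loocv_predict` predicts every record
from the other n−1 (diagonal of the distance matrix set to +inf). With
`use_log` both features and response enter on the natural-log scale and
predictions are exponentiated before criteria are computed, so all models
are always compared on the original biomass scale. The allometric
reference in `compare_to_allometry` uses leave-one-out (PRESS) residuals
e/(1−h) by default so both methods are judged out of sample;
`sh_residuals="fit"` gives the in-sample comparison.

## Selection criteria

For residuals e = w − ŵ on the comparison scale: R² = 1 − RSS/TSS,
R²adj = 1 − (n−1)/(n−k)(1−R²), Syx = √(RSS/(n−k)) with k the model
parameter count, and AIC = n·ln(RSS/n) + 2k′, AICc = n·ln(RSS/n) +
2k′n/(n−k′−1), BIC = n·ln(RSS/n) + ln(n)·k′ with k′ = k+1 (the extra
degree of freedom is the residual variance). kNN has no parametric k; we
use the number of predictor variables in the configuration as a
transparent proxy (overridable via `n_params`). The small-sample rule
(n/k′ < 40) sets an advisory flag — both AIC and AICc are always reported,
never silently swapped. R² is not clamped: a model worse than the mean
predictor reports a negative value. A perfect fit (RSS = 0) reports the
information criteria as −inf with a warning.

## Residual diagnostics

Shapiro–Wilk W on the log-scale residuals (normality), White's LM = n·R²
from regressing squared residuals on the predictors, their squares and
cross-product (homoscedasticity; χ² reference with the auxiliary slope
count as df), and Durbin–Watson over record order (independence). The
package reports statistics and p-values and renders no verdict; record
order is the only ordering the data carry, and DW is meaningful only to
the extent that order is meaningful.

## Synthetic forests

The generator emulates destructive biomass samples from young
mixed-species restoration plantings (~2–6-year-old stands, dozens of
species):

| quantity | law | default | why |
|---|---|---|---|
| dbh (cm) | 1·25^Beta(1,1.6) | range 1–25 | bounded reverse-J: many small stems, few large — the classic young-stand shape; the log-scale draw keeps ln(dbh) well spread so the allometric fit is well conditioned |
| ht (m) | 1.9·dbh^0.55·e^N(0,0.4) | — | allometric height–diameter coupling; 40 % scatter reflects many species sharing a size class |
| dm (m) | 0.45·dbh^0.6·e^N(0,0.15) | — | crown diameter grows with stem size |
| hc (m) | ht·Beta(2,4) | — | crown base strictly inside (0, ht) |
| db (g/cm³) | (0.45 + 0.10·u_s)·e^N(0,0.08), clipped [0.2,0.9] | — | species-specific basic density; u_s is the species offset |
| da (g/cm³) | db·(1 + U(0.15,0.35)) | — | apparent density always exceeds basic density |
| w (kg) | exp(a + b·ln dbh + c·ln ht + N(0,σ)) | a=−1.390796, b=1.051491, c=1.084280, σ=0.3 | log-linear allometry with multiplicative lognormal error |

Heterogeneity mode (`n_species > 1`, `generate_two_regime`): species are
assigned uniformly; species s gets parameter offsets spread·u_s with u_s
evenly spaced on [−½, ½], default spread 0.5 on the exponent b (two
species differing by 0.5 in b) and a ±0.05 g/cm³ basic-density shift, so
the allometric regime is weakly identifiable through wood density — as
with real species-specific densities. All draws come from one seeded PCG64
stream and are bit-reproducible.

What the generator does **not** emulate: real species composition (it has
no taxonomy, only parameter regimes), measurement error in the predictors,
size-dependent (heteroscedastic) biomass error, and spatial or age
structure. Tests passing on these forests therefore show that the
machinery is correct and that the qualitative local-vs-global comparison
behaves as expected under controlled heterogeneity — not that any
particular real stand will show the same gains.

## Feature scaling and the heterogeneous-forest study

Whether to standardize coordinates before computing distances is a genuine
design fork. With raw mixed units, dbh (range ~1–25 cm) and ht dominate
every metric and the density coordinates (~0.2–0.9 g/cm³) are numerically
invisible; since, in the generator, density is the only feature that marks
the species regime, raw-unit kNN cannot exploit the heterogeneity and the
efficient global OLS fit wins (median Syx gain ≈ −8 % over 50 two-regime
replicates). With z-scored coordinates the density marker participates,
and the all-variable Chebyshev configuration with 1/d weighting peaks at
k = 5 with a positive median gain, an interior minimum of the Syx-vs-k
curve in ~80 % of replicates, and a clear loss to the allometric model on
noise-free log-linear stands. The replicate comparison study (and
`scripts/acceptance.py`) is therefore defined on standardized coordinates;
`KNNConfig` keeps `standardize=False` as its default to preserve the
benchmark protocol, and both behaviours are documented here because the
contrast is itself a finding: the Chebyshev advantage on heterogeneous
stands hinges on commensurate coordinates.

## Problem sizes

Unit and property tests run on 25–200-tree forests; Monte-Carlo checks use
200 replicates at n = 500 (coefficient recovery), 1000 replicates at
n = 200 (White-test size), and 50 replicates at n = 180–200 (gain and
neighbor-sweep studies). These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances while keeping the whole suite
in well under a minute.

## Known limitations

* The degrees-of-freedom proxy for kNN (variable count) is a convention;
  information criteria across model families should be read as ranking
  devices, not evidence weights.
* PRESS residuals for the allometric reference are exact on the log scale
  but back-transformation makes the original-scale comparison approximate
  in the same way the model's own predictions are.
* Criteria computed on different data sizes are not comparable; the grid
  reports them side by side and `rank_models` warns on mixed n.
* The generator's lognormal error is homoscedastic on the log scale;
  strongly size-dependent error would favor weighted regression, which the
  package deliberately does not implement.
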