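# Methods

## Problem setting

On hilly terrain the direct solar irradiance reaching a pixel scales with
the cosine of the effective solar incidence angle, `cos i`, a function of
solar zenith θ, azimuth φ, terrain slope α and aspect β. Uncorrected
reflectance therefore carries an illumination term unrelated to canopy
state. The package normalizes reflectance to a flat-terrain equivalent
before deriving canopy features and fitting LAI regression models.

## Terrain geometry

Slope and aspect come from Horn's 3×3 weighted finite differences, the
standard DEM-derivative estimator and stable under noise. Aspect uses the
GIS convention — azimuth of steepest descent, clockwise from north — which
is the convention the incidence formula requires: a slope with β = φ faces
the sun, and α = θ then gives cos i = 1. Flat cells (zero gradient) have
undefined aspect and take the limit cos i = cos θ. Border cells and cells
adjacent to nodata are flagged invalid rather than filled. Angles are
degrees at every interface and radians only inside trigonometry.

## Correction models and their empirical parameters

Three sun–canopy–sensor corrections are implemented (see README for the
formulas). All are identities on flat terrain and linear in ρ, properties
the test suite asserts directly.

* **SCS+C.** The diffuse-compensation constant is C = B/A from the OLS fit
  ρ = A·cos i + B per band. This estimator is exactly consistent with the
  SCS+C forward model only where cos α is constant across the fitted
  pixels: with variable slope the model denominator cos θ·cos α + C varies
  per pixel and the fitted B/A acquires a geometric bias that grows with
  the spread of cos α (tens of percent on strongly variable-slope scenes in
  our measurements). This is a property of the estimator, not of the
  implementation; users fitting C on real DEMs should prefer masks covering
  terrain of similar gradient. The fit mask is a configurable input.
* **Minnaert+SCS.** The printed log-linear form ln ρ = ln ρ_c +
  k·ln(cos i/cos θ) omits the slope term that the correction formula itself
  implies. `fit_k` therefore defaults to regressing ln(ρ·cos α) on
  ln(cos i/cos θ) — the exact log-linearization of the correction, which
  makes the fit/correct round trip exact on noise-free forward scenes — and
  offers `slope_adjusted=False` for the literal form.
* **Numerical safeguards.** Pixels with cos i ≤ 0.01 are masked (the
  correction factor diverges in deep shadow); factors outside [0.2, 5] are
  counted per band as over-correction but still applied; corrected
  reflectance is re-clipped to [0, 1] with clip counts recorded. The
  degenerate-slope tolerance for |A| is 1e-8.

## Effectiveness statistics

Per band and method the report gives mean and sample Std (n−1 denominator)
over valid pixels, a two-sided paired t-test on pixel differences, a
two-sided variance-ratio F-test at (n−1, n−1) degrees of freedom, the R²
of reflectance on cos i, and relative changes 100·(after−before)/before.
Zero-variance differences make the t statistic undefined; the all-zero case
reports (0, 1) and the constant-nonzero case (NaN, 0), both flagged rather
than silently infinite. Rendered output rounds percentages to one decimal
and reflectance statistics to five, matching the precision such band
tables are normally printed at. Tests are per band; no spatial
autocorrelation adjustment is applied.

## Features

The 61-feature vector is 5 band means + 16 vegetation indices + 40 texture
values in a fixed, validated column order. Texture is computed per pixel on
a 3×3 window after 64-level quantization over the band's global valid range
(global bounds keep texture comparable across the scene), with symmetric
normalized co-occurrence matrices at distance 1 in four directions (0°,
45°, 90°, 135°) averaged. Windows truncate at raster edges; a direction
with fewer than two valid pairs at a pixel is flagged missing. Zero-variance
windows take Correlation = 0 by convention (the 0/0 case). Entropy uses the
natural logarithm. An exhaustive pair-enumeration oracle in the test suite
verifies all eight metrics in all four directions on every window of a
seeded image.

Canopy membership is pixel-center-in-geometry; point samples are buffered
(default 0.5 m). Per-canopy texture is the mean of the per-pixel metric
over canopy pixels — computing texture per pixel first keeps the metric
definition independent of canopy size. Normalization to [−1, 1] is min–max;
inside cross-validation it is refit on each training split by default
(leakage-safe), with an all-rows mode available since either protocol is
defensible for a fixed survey. Held-out values outside the training range
are deliberately not clipped.

## Reference LAI

The specific-leaf-weight formula is implemented literally:
LAI = (W₂/W₁)·(S·M)/A with elliptical canopy area. Note the formula scales
the leaf mass of the sampled stems to the whole plant through the stem
count M without dividing by the number of sampled stems; the generator
back-solves its field records through the same formula, so the convention
is self-consistent end to end. Units (g, m², m) and positivity are enforced
at parse time with row-level messages. Directly supplied reference LAI
takes precedence over recomputation.

## Models and evaluation

Estimator fitting is delegated to scikit-learn (LR, DT, RF) and xgboost;
the package owns fold construction (seeded uniform shuffle, no
stratification), exhaustive grid search scored by mean CV RMSE with ties
broken toward fewer estimators then shallower depth, and the metric
definitions (r² = 1 − SSE/SST; nRMSE = 100·RMSE/range(observed), pooled
range by default with a per-fold option; Bias = mean(predicted−observed),
negative = underestimation). Default grids are small supersets of
hyperparameter optima reported for this kind of canopy data (DT depth ≤ 10,
RF 100–200 trees with sqrt/log2 features, XGBoost 200 trees at depth 5–7
and learning rate 0.01–0.1). Fold means and pooled out-of-fold predictions
are both exposed.

## Attribution

Predictions decompose as f(x) = φ₀ + Σφᵢ with φ₀ the background-mean
prediction (the training table by default; the reference distribution is a
genuine modelling choice and is therefore explicit). Linear models use the
closed form βᵢ(xᵢ − x̄ᵢ). Trees and forests use the exact path
decomposition: walking each sample's decision path, the change in node
mean value at every split is credited to the split feature. For the
boosted model the same decomposition runs over the booster's dumped trees
in double precision, with internal-node expectations as cover-weighted
child means and float32 threshold comparisons to reproduce the booster's
routing; the independent float64 leaf-sum walk is checked against the
booster's own predictions. Additivity holds to ~1e-14 and is asserted for
every family. Global importance is mean |φ| per feature, descending, ties
by name; a tidy (sample, feature, value, φ) table is exported so summary
plots are machine-checkable.

## Synthetic scenes: what they emulate, and what they do not

Defaults: 128×128 grid at 4 m cells (512 m extent), elevations rescaled to
58–186 m, solar zenith 23.3°, azimuth 157.8°, five-band base reflectance at
the magnitudes typical of tea canopies (Blue 0.064 … NIR 0.258), 90
samples, truncated log-normal LAI on [1.04, 9.45] with mean 3.81 and
CV 0.557, pixel noise 0.003.

* **DEM.** A superposition of constant-gradient conical hills: slope
  magnitude is spatially uniform while aspect sweeps the full compass. This
  gives a dissected-hill landscape on which the C and k estimators are
  statistically consistent (see above); it does not emulate the
  variable-gradient micro-topography of real plantations, where those
  estimators carry the documented bias.
* **Forward model.** Observed reflectance is true reflectance times the
  exact algebraic inverse of the chosen correction (per-band true C or k;
  diffuse fraction larger in the visible bands), plus iid Gaussian noise.
  Factors outside [0.1, 10] abort generation as a configuration error.
* **Sampling design.** Samples are placed in elevation strata as matched
  shaded/sunlit aspect pairs with similar canopy density, emulating a
  balanced stratified field survey; illumination and LAI are crossed rather
  than confounded.
* **Canopy coupling.** A saturating map f = 1 − exp(−0.45·LAI) raises NIR
  and red-edge and darkens the visible bands (so vegetation indices rise
  and saturate with LAI), and within-canopy multiplicative speckle with
  standard deviation increasing in LAI emulates gap/self-shadow structure
  (so texture features carry genuine signal; a `texture_dominant()` preset
  makes structure the dominant driver). Background variation is pixel-iid:
  a smooth background field would alias onto cos i in a single realization
  and bias the parameter fits.
* **Scale compression.** Real surveys image centimetre pixels over hundreds
  of metres; at desk scale the cells are 4 m and canopy footprints are
  enlarged (radius 8–12 m) so each spans enough pixels for texture
  statistics. Field records (W₁, W₂, S, M, d₁, d₂) are back-solved so the
  specific-leaf-weight formula reproduces each drawn LAI exactly.
* **Not emulated:** radiative-transfer canopy optics, cast shadows,
  spatially correlated noise, cultivar effects, multi-date scenes. Passing
  tests demonstrate internal consistency and recoverability under the
  generator's assumptions, not retrieval accuracy on real imagery; the
  accuracies a real survey reports require the original imagery and field
  data.

## Problem sizes and determinism

The default test suite and the acceptance script use 128×128 scenes for the
end-to-end pipeline and 256×256 for radiometric parameter-recovery checks,
five-fold CV on 90 samples, 2000 replicates for the F-test calibration, and
complete in a few minutes on one CPU. Every random draw flows from a single
integer seed through `numpy.random.default_rng`; scenes, fold assignments
and model fits are bit-reproducible given (config, seed).

## Known limitations

* The C and k estimators are consistent only on terrain of uniform
  gradient; on real variable-slope DEMs both acquire geometric bias and the
  ordinary-least-squares R² diagnostics should be inspected.
* OLS linear regression with 61 features on ~72 training rows is nearly
  saturated; its cross-validated skill is volatile and its
  corrected-vs-uncorrected comparison can flip sign between seeds, unlike
  the tree ensembles, which improve consistently.
* Per-canopy texture aggregation (pixel-level metrics averaged over the
  canopy) is one of several defensible conventions; computing a single
  co-occurrence matrix per canopy patch would weight pairs differently.
* The paired t-test treats pixels as independent; spatial autocorrelation
  inflates its significance, so its p-values should be read as descriptive
  at scene scale.
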