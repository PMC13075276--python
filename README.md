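# tealai

Terrain-corrected UAV multispectral retrieval of tea-canopy Leaf Area Index
(LAI) for plantations on hilly terrain.

In mountainous plantations, slope and aspect modulate the solar irradiance
reaching each pixel, so surface reflectance mixes canopy signal with
illumination geometry and degrades LAI retrieval. `tealai` implements the
full analysis chain that addresses this:

1. **Terrain geometry** — slope α and aspect β from a DEM (Horn 3×3 kernel)
   and the effective solar incidence cosine per pixel,
   `cos i = cos θ cos α + sin θ sin α cos(φ − β)`,
   for solar zenith θ and azimuth φ.
2. **Topographic correction** of five-band reflectance ρ (Blue, Green, Red,
   Red-edge, NIR):
   - SCS: `ρ_c = ρ · cos α cos θ / cos i`
   - SCS+C: `ρ_c = ρ · (cos θ cos α + C)/(cos i + C)` with per-band
     `C = B/A` from the image-wide regression `ρ = A·cos i + B`
   - Minnaert+SCS: `ρ_c = ρ · (cos θ / cos i)^k · cos α` with per-band `k`
     from a log-linear regression.
3. **Correction effectiveness report** — per band and method: mean and Std
   of reflectance before/after (paired t and variance-ratio F tests), the
   R² of reflectance against cos i, and relative changes in percent.
4. **Canopy features** — a 61-dimensional vector per sampled plant: 5 band
   means, 16 vegetation indices (NDVI, EVI, SAVI, OSAVI, …), and 40 GLCM
   texture metrics (8 Haralick statistics × 5 bands; 3×3 window, 64 gray
   levels, four directions averaged), min–max normalized to [−1, 1].
5. **Reference LAI** from field measurements by the specific-leaf-weight
   method, `LAI = (W₂/W₁)·(S·M)/A` with elliptical canopy area
   `A = π(d₁/2)(d₂/2)`.
6. **Models** — LR, Decision Tree, Random Forest and XGBoost under grid
   search with five-fold cross-validation; R², RMSE, nRMSE, MAE, Bias.
7. **Attribution** — exact additive per-feature decomposition
   `f(x) = φ₀ + Σ φᵢ` (closed form for LR, tree-path decomposition for the
   tree ensembles) and global importance by mean |φ|.

A synthetic-scene generator (`tealai.synthetic`) produces DEMs, forward-
distorted reflectance with known correction parameters, and 90 canopy
samples with a right-skewed LAI distribution (mean ≈ 3.8, CV ≈ 0.56), so
every stage is validated by parameter recovery with full ground truth.

## Worked example

```python
import tealai

result = tealai.run_pipeline(tealai.SceneConfig(seed=0))

print(result.illumination_r2.round(4))
print(result.cv_results.round(3)[["family", "regime", "r2", "rmse", "nrmse"]])
```

```
         before   after
band
Blue     0.2447  0.0001
Green    0.5450  0.0001
Red      0.1450  0.0001
RedEdge  0.5427  0.0000
NIR      0.4208  0.0000
    family       regime     r2   rmse   nrmse
0       LR  uncorrected  0.810  0.643   8.816
1       LR    corrected  0.895  0.500   6.856
2       DT  uncorrected  0.743  0.823  11.273
3       DT    corrected  0.839  0.641   8.788
4       RF  uncorrected  0.841  0.646   8.856
5       RF    corrected  0.890  0.535   7.335
6  XGBoost  uncorrected  0.835  0.658   9.011
7  XGBoost    corrected  0.882  0.547   7.494
```

The first table shows that SCS+C correction removes the dependence of
reflectance on illumination geometry (R² against cos i drops from up to
0.55 to ≤ 0.0001). The second shows five-fold cross-validated skill of the
four model families on the same 90 samples: every family retrieves LAI
more accurately from terrain-corrected features (e.g. XGBoost RMSE drops
from 0.66 to 0.55 LAI units, nRMSE from 9.0% to 7.5%).

The same stages are available from the shell:

```bash
tealai simulate --seed 0 --out scene
tealai correct --stack scene_observed.tif --dem scene_dem.tif \
       --zenith 23.3 --azimuth 157.8 --method scs+c --out corrected.tif
tealai features --stack corrected.tif --samples scene_samples.csv \
       --point-buffer 10 --out features.csv
tealai train --features features.csv --family XGBoost --out cv.csv
```

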