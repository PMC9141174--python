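# hazegrid

Satellite-style dark-target AOD retrieval, seasonal AOD→PM2.5 regression,
population exposure risk, and LISA spatial-cluster mapping on 1-km grids —
with a synthetic-scene module so the whole chain is testable against known
ground truth.

## The problem

Ground monitoring networks measure PM2.5 accurately but sparsely, and
station interpolation misses the spatial detail that exposure assessment
needs. Satellite reflectance imagery offers daily 1-km coverage, but what it
sees is aerosol optical depth (AOD), not surface concentration. `hazegrid`
implements the full chain from reflectance to risk for researchers in air
quality and environmental health:

1. **Dark-target AOD retrieval.** Over dark vegetated surfaces the 2.1 µm
   band is nearly aerosol-free, so its apparent reflectance estimates the
   surface; visible surface reflectances follow from the fixed ratios
   ρ_red = ρ₂.₁/2 and ρ_blue = ρ₂.₁/4. The 550-nm optical depth τ is then
   the unique solution of

   ρ* = ρa(τ) + T(τ)·ρ / (1 − ρ·s(τ)),

   matched per visible band against a lookup table of atmospheric functions
   on a geometry × τ grid (zeniths 0–60° step 12°, azimuths 0–180° step
   24°, τ ∈ {0, 0.25, 0.5, 1.0, 1.5, 1.95}). Daily fields composite to
   monthly and seasonal means. Ground sun-photometer AOD is moved to 550 nm
   with the Angstrom law τ(λ) = β·λ^−α for verification (Pearson/Spearman,
   mean/SD).

2. **Seasonal AOD→PM2.5 models.** Collocated (AOD, PM2.5) samples are split
   chronologically per season; six families — linear, logarithmic,
   exponential, power, quadratic, cubic — are fitted and the best is chosen
   by verification R²/RMSE with a parsimony near-tie rule. The selected
   model maps seasonal AOD composites to PM2.5 grids (µg/m³).

3. **Exposure risk.** Qᵢ = Pᵢ·Mᵢ / mean(P·M) combines population density
   and concentration into a relative risk with mean 1, classified into six
   levels from *extremely safe* (Q = 0) to *extremely dangerous* (Q > 5).

4. **Spatial clustering.** Global and local Moran's I with conditional
   permutation inference label significant high-high (HH) and low-low (LL)
   agglomerations of risk — the map that tells policy where exposure
   concentrates.

A synthetic-scene module generates spatially autocorrelated AOD fields,
PM2.5 truth under the seasonal laws, clustered station networks,
multi-center population surfaces and cloud masks, so every stage has a
parameter-recovery test. See `docs/methods.md` for models, assumptions and
limitations.

## Worked example

`examples/` contains one short script per capability. The full chain
(`python examples/05_full_pipeline.py`) synthesizes four seasons of daily
scenes on a 40×40 km grid, retrieves and composites AOD, fits and selects
seasonal models, and maps risk:

```
selected seasonal models:
  spring  power        (57.398, 0.690)  R2(verify) = 0.950
  summer  exponential  (13.775, 0.903)  R2(verify) = 0.897
  autumn  power        (62.863, 0.570)  R2(verify) = 0.932
  winter  power        (78.260, 0.409)  R2(verify) = 0.890

prediction accuracy vs generating truth (median relative error):
  spring  1.9%
  summer  1.0%
  autumn  1.4%
  winter  1.4%

mean exposure risk Q = 1.000000, max = 2.86
risk level counts: {'safe': 874, 'relatively safe': 671, 'relatively dangerous': 55}
global Moran's I of risk = 0.9730
LISA clusters: {'NS': 800, 'HH': 387, 'LL': 413, 'LH': 0, 'HL': 0}
```

The selected families and coefficients recover the generating seasonal laws
(power in spring/autumn/winter, exponential in summer); predicted PM2.5
grids match the truth within ~2% at the cell level; risk has mean 1 by
construction; and the densely populated synthetic "cities" emerge as
significant HH clusters.

The same stages are scriptable from the shell:

```bash
hazegrid run --config examples/demo_config.yaml --out runs/demo
hazegrid validate                 # verification stats of the packaged table
hazegrid lisa runs/demo/risk_q.tif --out-prefix runs/demo/lisa
```

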