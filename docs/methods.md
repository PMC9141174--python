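# Methods

This note documents the models, numerical choices and limitations behind
`hazegrid`. The package estimates gridded PM2.5 from multiband reflectance
scenes by dark-target aerosol retrieval, calibrates seasonal AOD→PM2.5
regressions against station data, and assesses population exposure risk with
spatial-cluster mapping. Because the real satellite, sun-photometer, station
and population inputs such a study uses are not redistributable, a
first-class synthetic-scene module generates all inputs with known ground
truth; every claim the test suite makes is a parameter-recovery claim
against that truth.

## Dark-target retrieval

The apparent (top-of-atmosphere) reflectance over a Lambertian surface of
reflectance ρ under an aerosol layer of optical depth τ is

ρ*(μ, μ₀, φ) = ρa + T·ρ / (1 − ρ·s),

with ρa the atmospheric path reflectance, T = T(μ₀)·T(μ) the two-way
transmittance product, s the atmospheric spherical albedo, and μ, μ₀ the
cosines of the satellite and solar zenith angles. Over dark vegetated
surfaces the 2.1 µm band is nearly transparent to fine-mode aerosol, so its
apparent reflectance estimates the surface; the visible surface reflectances
follow from the fixed ratios ρ_red = ρ_2.1/2 and ρ_blue = ρ_2.1/4. Retrieval
then solves ρ*_model(τ) = ρ*_observed per visible band and averages the red
and blue solutions (the merge rule when both bands succeed; if one fails its
partner's solution is used).

### The parametric atmosphere

A full radiative-transfer code is deliberately not reimplemented. The
atmospheric functions default to a single-scattering-style parametric family

- ρa(τ, g, λ) = A(g, λ)·(1 − T), A = C·P(Θ)/(μ + μ₀),
- T(τ, g, λ) = exp(−b·τλ·(1/μ + 1/μ₀)/2),
- s(τ, λ) = c·(1 − exp(−τλ)),

with P(Θ) = ¾(1 + cos²Θ) a Rayleigh-type phase function of the scattering
angle and τλ = τ₅₅₀·(λ/550 nm)^−α the band optical depth under an Angstrom
scaling (α = 1.8, a fine-mode value). Constants C = 0.4, b = 0.4, c = 0.25
are chosen so that the clean-atmosphere limits (ρa(0) = 0, T(0) = 1,
s(0) = 0), strict monotonicity in τ, and s < 1 all hold. Sharing the
exponential T between ρa and the transmittance makes ρ*(τ) provably strictly
increasing for any surface darker than A/(1 + s·ρ) ≈ 0.145 — covering the
whole dark-pixel admissible range (ρ_red ≤ 0.125 at the 2.1 µm screen of
0.25) — which guarantees a unique retrieval root.

The 2.1 µm band is treated as exactly aerosol-transparent (ρa = 0, T = 1,
s = 0). This idealization makes the dark-target surface identity exact in
the synthetic world, so forward-then-invert consistency can be tested to
solver precision; with a real atmosphere the residual 2.1 µm aerosol signal
would add a small positive AOD bias that this package does not model. The
monotonicity invariants are therefore asserted for the aerosol-active
visible bands. The lookup-table interface accepts externally tabulated
values, so a table computed by a real transfer code can be dropped in
unchanged.

### Lookup table and inversion

The default LUT axes are satellite/solar zenith {0, 12, 24, 36, 48, 60}°,
relative azimuth {0, 24, …, 168, 180}° (regular 24° steps with the 180°
endpoint appended), τ₅₅₀ {0, 0.25, 0.5, 1.0, 1.5, 1.95} and bands
470/660/2100 nm. Interpolation is multilinear on the four continuous axes
and nearest (exact) on band; it is exact at nodes, and the median relative
error of interpolated TOA reflectance against direct forward evaluation is
under 2% over the span. Because the interpolated forward curve at fixed
geometry is piecewise **linear** in τ, each cell's τ is solved exactly per
segment in a vectorised pass — equivalent to bisection on the same
objective to arbitrary tolerance, but orders of magnitude faster.
Observations brighter than the τ = 1.95 node clip to 1.95 (the stated
retrieval range); observations darker than the clean-atmosphere node are
unretrievable (nodata), as are cloud-masked cells and cells failing the
dark-pixel screen (ρ_2.1 > 0.25).

Cloud screening is a proxy, not an operational product: a cell is cloudy if
its blue apparent reflectance exceeds 0.4 or the local 3×3 standard
deviation exceeds 0.08. On synthetic bright-blob clouds its recall is ≥ 95%;
nothing more is claimed.

Compositing averages daily fields to monthly means and monthly means to
seasonal means (not a pooled daily mean — the two differ when coverage is
uneven across months); a composite cell is valid if any input is valid, so
cloud-blocked days simply drop out cellwise. Seasons follow the study
design: spring = Mar–May, summer = Jun–Aug, autumn = {Sep, Nov}, winter =
{Feb, Dec}; January and October are unmapped (no usable coverage in the
source campaign) and are excluded by season-aware stages.

## Ground validation

Multi-wavelength sun-photometer AOD is moved to 550 nm via the Angstrom law
τ(λ) = β·λ^−α (λ in µm), fitted by log-log least squares over all channels
(exact for power-law data). Collocation is exact-cell, exact-calendar-day.
Verification uses the Pearson correlation, the Spearman rank correlation
(the 1 − 6Σd²/(n(n²−1)) shortcut without ties; Pearson on mid-ranks with
ties, since the shortcut is a no-ties identity), and mean/SD summaries with
the **sample** (n−1) standard deviation — the convention that reproduces
the packaged reference table's printed values. A 21-record collocation
table from a 2016 two-site coastal campaign ships with the package; its
summary statistics (R = 0.781, means 0.634/0.580, SDs 0.334/0.328) are
regression-tested at three decimals.

## Seasonal AOD→PM2.5 models

Six families are fitted per season: linear, logarithmic (a₀ + a₁ln x),
exponential (a₀e^{a₁x}), power (a₀x^{a₁}), quadratic and cubic. Polynomial
and logarithmic families use ordinary least squares; exponential and power
use least squares on (x, ln y) and (ln x, ln y) back-transformed, which is
exact on noise-free generating data (an iterative refinement on the
original scale is available behind `refine=True`). Power and logarithmic
families require x > 0; prediction returns nodata there and floors negative
predictions at zero.

Goodness of fit is R² = 1 − SSE/SStot on the original y scale (for OLS
linear fits this equals the explained-over-total form and the squared
Pearson correlation of fitted versus observed; unlike the explained-sum
form it is bounded by 1 for back-transformed nonlinear fits). The F
statistic is the regression F with p = number of predictor terms. RMSE uses
the n denominator.

Samples are split chronologically per season (default 70% build); an
optional outlier rule eliminates verification rows whose absolute
standardized residual under the best preliminary build fit exceeds 3, and
reports them rather than silently dropping them. Min-max normalization of
the predictor is available (`normalize_x=True`), fitted on the build set
and frozen for verification and prediction; the default is raw AOD, which
keeps stored coefficients in physical units.

**Selection.** Candidates are scored by verification R² (equivalently
RMSE — on a common verification set the two order identically). Scores
within 0.01 of the best are treated as tied and resolved by parsimony, then
RMSE. The tolerance matters: the structural R² gap between a power law and
its best linear approximation over a realistic right-skewed AOD sample is
only ≈ 0.012, so a strict argmax lets 3–4-coefficient polynomials win
verification-noise coin flips against the generating 2-coefficient law.
With the near-tie rule and seasonal samples of ~400 collocations (41
stations × 12 days), the generating family is recovered in ≥ 90% of noisy
replicates; at ~120 samples no honest verification-set selector achieves
that rate.

## Exposure risk

The relative exposure risk is Qᵢ = Pᵢ·Mᵢ / mean(P·M), with Pᵢ population
density (persons/km²) and Mᵢ PM2.5 (µg/m³); the mean runs over cells valid
in both inputs, so mean(Q) = 1 by construction and Q is invariant to
rescaling either input. Annual risk uses the annual-mean PM2.5 surface
(mean of the four seasonal predictions), not the mean of seasonal Q maps.
Classification uses six levels on half-open intervals closed on the right —
0; (0,1]; (1,2]; (2,3]; (3,5]; (5,∞) — the only reading under which the
levels tile [0, ∞). Regional aggregation is the unweighted mean of cell Q
values per region label.

## Spatial autocorrelation

Weights are rook (4-) or queen (8-) contiguity among valid cells —
default queen, row-standardized; nodata cells are removed from the graph
entirely and isolated cells are flagged and excluded from statistics.
Global Moran's I = (n/S₀)·Σᵢⱼwᵢⱼzᵢzⱼ/Σzᵢ² with z the mean deviations; the
local statistic is Iᵢ = zᵢ/S²·Σⱼwᵢⱼzⱼ with S² the sample (n−1) variance,
and ΣIᵢ = I·S₀(n−1)/n is checked as an invariant. Both match a literal
double-loop evaluation to 1e−12, and the 2-colour checkerboard gives
exactly −1 under rook row-standardized weights.

Inference is by conditional permutation: cell i's value is held fixed while
its neighbours draw values without replacement from the other n−1 cells
(999 draws by default; one shuffled donor array per cell indexed by a
shared without-replacement index matrix). The p-value is two-sided with the
+1 correction, p = (#{|I*| ≥ |Iᵢ|} + 1)/(n_perm + 1). On white noise the
empirical rejection rate at α = 0.05 is ≈ 0.048 (within [0.03, 0.08] over
20 seeds at 999 permutations on a 20×20 grid). Cluster labels are NS where
p > α, else the quadrant of (zᵢ, lagᵢ − mean lag): HH, LL, HL, LH. Note
that under conditional permutation a low cell inside an overwhelming
low-value majority is *expected* to have a low lag and is therefore not
significant — LL/HH significance requires the local homogeneity to be
unusual against the global value mix. Analytical (normality/randomization)
variances are intentionally not provided.

## Synthetic data: what it emulates, and what it does not

- **AOD fields**: Gaussian-smoothed white noise plus a deterministic linear
  gradient (default eastward, emulating coastal-high/inland-low structure),
  clipped to [0, 1.95]. Smoothness ≥ 5 cells yields strong positive global
  Moran's I (permutation p < 0.01). Real retrieval fields additionally have
  swath geometry, retrieval-error correlation and orographic structure.
- **PM2.5 truth**: the seasonal generating laws default to the package's
  seasonal best-fit relations (power in spring/autumn/winter, exponential
  in summer) with mean-one multiplicative lognormal noise — concentrations
  are positive and the plausible families are log-scale-linear, so
  lognormal is the natural noise model. Observation dropout is Bernoulli
  per record with no temporal correlation.
- **Stations**: 2 AOD + 41 PM2.5 sites by default; with clustering > 0,
  placement probability mixes uniform with (lightly smoothed) population
  density, emulating networks concentrated in developed areas.
- **Population**: sums of exponential kernels around random centers
  (default 5 centers, 8000 persons/km² peak, 6 km decay).
- **Scenes**: visible surface reflectances follow the dark-target ratios
  exactly, and the 2.1 µm band is aerosol-free, so retrieval errors in the
  synthetic study isolate LUT interpolation — passing tests demonstrate the
  machinery's internal consistency, not the field accuracy of dark-target
  retrieval on real surfaces (which degrades over bright surfaces and
  depends on the aerosol model).

Defaults follow the conditions the package's seasonal cycle encodes: AOD
base levels 0.65/0.55/0.50/0.35 for winter/spring/autumn/summer
(winter-high, summer-low), observation noise_cv 0.1 as a convention (the
packaged demo uses 0.05), cloud fraction 0.08.

## Problem sizes and reproducibility

The packaged demo runs a 40×40 km grid with 12 dates per season (48 scenes)
and 199 LISA permutations, completing in seconds on one CPU; unit and
acceptance tests use grids between 3×3 and 50×50 and 999 permutations where
calibration is measured. One master seed fans out to per-stage seeds via
`numpy.random.SeedSequence`, making every pipeline rerun bit-identical.
`scripts/acceptance.py` recomputes all headline quantities from scratch at
any seed.

## Known limitations

- No real L1B ingestion: radiometric calibration, orbital geometry rasters,
  HDF parsing, and map-projection handling beyond an affine grid-to-world
  transform are out of scope; scenes arrive as aligned GeoTIFFs.
- The parametric atmosphere is a stand-in: no gas absorption, polarization,
  BRDF surfaces or aerosol-type mixtures; which aerosol model a real table
  would assume is left to the table supplier.
- The cloud screen is a brightness/uniformity proxy.
- No health-burden conversion: the analysis stops at relative exposure
  risk, without concentration-response functions.
- Kriging of station PM2.5 (an alternative interpolation surface) is not
  implemented.
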