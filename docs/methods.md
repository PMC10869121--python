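# Methods

This note records the models, parameter choices and numerical decisions behind
`burnhsi`, and what the synthetic-data tests do and do not demonstrate.

## Skin optical model

Two plane-parallel layers under air: a 100 µm epidermis over a semi-infinite
dermis, both with refractive index n = 1.4, Henyey–Greenstein anisotropy
g = 0.9, and reduced scattering µs′(λ) = 45.3·(λ/500 nm)^−1.292 cm⁻¹ (a
typical dermis power law); µs = µs′/(1−g). Epidermal absorption is melanin,
µa = (Cm/100)·µ_mel(λ); dermal absorption is blood,
µa = ln(10)·(150/64500 mol L⁻¹)·Σᵢ (Cᵢ/100)·εᵢ(λ) over the hemoglobin species,
using the convention that CHbT = 100 vol.% means whole blood carrying 150 g/L
hemoglobin (tetramer molar mass 64 500 g/mol). Both layers carry a constant
background absorption of 0.2 cm⁻¹ representing bloodless, melanin-free tissue;
besides being physically sensible, it guarantees photon histories terminate.
All of these are fields of `SkinModel` and configurable.

The packaged extinction table (`data/extinction_default.csv`, 450–700 nm at
10 nm) follows the standard compilations for oxy-/deoxy-hemoglobin, a
Zijlstra-style tetramer-basis methemoglobin spectrum with its diagnostic
600–650 nm band, and an interior-melanosome power law 6.6·10¹¹·λ^−3.33 cm⁻¹
for melanin. The loader resamples linearly onto any requested grid and
sanity-checks positivity and the metHb band on load.

## Photon transport

`run_transport` is a standard multi-layer MCML-style kernel: pencil beam at
normal incidence, specular deduction, hop–drop–spin with exact Fresnel
reflection/refraction and total internal reflection, Russian roulette
(threshold 10⁻⁴, survival 0.1). Weight bookkeeping is exact: roulette gains
and losses are folded into the absorption ledger, so specular + diffuse
reflectance + transmittance + absorption = 1 to float precision — this is
asserted to 10⁻⁶ in the tests. Randomness is a self-contained xorshift64*
generator (seeded via splitmix64), making runs bit-reproducible for a given
seed and independent of numpy's global state.

`sample_pathlengths` runs the same geometry with zero absorption and records
each escaping photon's per-layer path length L. Diffuse reflectance for *any*
absorption vector then follows by Beer–Lambert reweighting,
Rd = (1−r_sp)·⟨exp(−Σ_l µa_l L_l)⟩, which is exact in expectation — one
scattering simulation per wavelength serves the entire calibration grid. The
estimator degrades at high absorption (few histories have short enough dermal
paths), so the calibration draws several path samples per band with different
dermal path caps: capped histories are discarded, which is unbiased once
cap·µa exceeds ~8 (the discarded weight is < e⁻⁸), and a capped run is many
times cheaper per photon, so strongly absorbed evaluations can afford 10–25×
more photons. Default tiers (cap cm, photon multiplier, µa validity bound):
(60, 2, 0), (12, 4, 0.7), (4, 10, 2), (1.3, 25, 18). Every tier valid at a
grid point contributes through inverse-variance weighting; because the weights
vary continuously with absorption, the sampled Rd surface has no tier-boundary
discontinuities for the downstream polynomial fit to amplify — an earlier
hard-switch design produced exactly such kinks and destabilized the inversion.

## Calibration grid and empirical formulas

The calibration grid is a tensor product over Cm ∈ {0, 5, 10},
CHbO ∈ {0, 2, 4, 7, 10, 15, 20, 35, 50, 70, 85, 100},
CHbR ∈ {0, 2, 4, 7, 10, 15, 20, 30, 45} and
CmetHb ∈ {0, 1, 2, 4, 7, 10, 15, 20, 30} vol.% (2916 points). Two features of
the axes matter. They are *dense at low concentrations*: the reflectance
surface is strongly convex there, and multilinear interpolation across coarse
cells produces spectra that are mixtures of exponentials rather than spectra
of any single concentration — such mixtures invert to badly biased estimates
even without noise (grid density is nearly free, since the photon transport
cost is per band, not per grid point; reweighting runs in float32 and in
record chunks to bound memory). And the CHbO axis extends to 100 vol.% so the
inversion covers the whole-blood definitional anchor (CHbT = 100); tensor
corners whose species sum exceeds 100 vol.% are unphysical but retained as
interpolation scaffolding (the transport model accepts any µa). Each grid
spectrum is unmixed by the same windowed OLS as real data, giving
(truth, coefficients) pairs.

The empirical formulas are one polynomial per chromophore in the five
regression coefficients, default degree 3, fitted by least squares with three
stabilizing choices, all made from recovery accuracy measured on independent
validation simulations:

- **Input standardization.** Raw coefficients span orders of magnitude; an
  unscaled cubic design is numerically singular.
- **Fit domain capped at CHbT ≤ 130 vol.%.** The supra-physiologic corners
  strain a global polynomial; the margin above 100 stabilizes the fit at the
  whole-blood boundary.
- **Noise augmentation.** The extinction predictors are nearly collinear over
  550–680 nm, so the coefficient vector amplifies spectral noise along
  ill-conditioned directions; each record is replicated 30× with i.i.d.
  Gaussian absorbance noise (SD 0.001) re-projected through the unmixing
  operator before fitting, which regularizes those directions at the noise
  level the pipeline actually sees. Larger augmentation (≥0.0025) visibly
  shrinks high-CHbT estimates toward the mean; smaller leaves the fit chasing
  the calibration's own noise realization.

Held-out RMSE is reported from an every-5th-record split after a deterministic
shuffle — a plain stride aliases with the 5-long grid axes (it would hold out
the entire CmetHb = 0 face). Because all grid points within a band share
photon paths, their errors are correlated and held-out RMSE understates error
on independent spectra; the acceptance checks therefore probe recovery with
*independently simulated* spectra.

Negative formula outputs are clamped to zero with a flag; inputs outside the
training bounding box set an extrapolation flag rather than raising.

One global polynomial cannot serve both a whole-blood-reach inversion and
noisy per-pixel imaging optimally, so two named fit profiles are provided
(`FIT_PROFILES`). `full-range` (degree 3, domain ≤ 130 vol.%, augmentation SD
0.001) reaches CHbT = 100 and suits high-precision single spectra such as the
anchor check. `imaging` (degree 3, domain ≤ 35 vol.%, augmentation SD 0.003)
matches the regularization to per-pixel sensor noise and the domain to the
physiologic imaging range; on synthetic wound cubes across all twelve
class/time conditions it recovers ROI-mean CHbT to ~2 vol.% and the
saturations (as ratios of ROI means) to ~3–5 points, where the full-range fit
errs several-fold more. Profile selection is a calibration-time choice, like
choosing a gain range on an instrument.

## Information limits of the inversion

Two regimes bound what recovery accuracy is achievable. At high perfusion the
550–590 nm bands saturate (reflectance floors near the epidermal backscatter
level ~0.05) and CHbO sensitivity survives only around 590–640 nm; propagating
the per-band Monte Carlo noise through the five-coefficient bottleneck gives a
single-spectrum CHbT noise floor of roughly 4–8 vol.% at CHbT ≳ 50 even with
absorbance noise held to ~0.001–0.002. At very low perfusion (CHbT ≲ 15) the
spectral contrast itself is small against sensor noise. The whole-blood anchor
check (±10% relative at CHbT = 100) sits comfortably above this floor with the
default budgets; per-spectrum guarantees much tighter than ~10% relative and
~5 saturation points do not, which is why the end-to-end recovery test asserts
medians at those levels with bounded outliers rather than per-vector bounds.
ROI statistics in imaging use average thousands of pixels and are much tighter;
for the saturations the ratio-of-ROI-means is preferred over the ROI-mean-of-
ratios, which is biased where noisy CHbT approaches zero.

## Unmixing

OLS of A(λ) on {ε_HbO, ε_HbR, ε_metHb, µ_mel, 1} over 550–680 nm inclusive
(14 bands at 10 nm). The intercept absorbs the wavelength-flat part of
scattering loss; R² is computed against the intercept-only model; residual
orthogonality to the predictors is tested against an independently coded
normal-equations solve. Per-pixel maps vectorize the same solve over all
valid pixels at once; masked pixels carry NaN through every product. Pixels
with CHbT = 0 report StO2 = StMet = 0 with an `undefined` flag (kept
renderable, honestly flagged) and are sentinel-labeled, never classified.
Reflectance is floored at 10⁻⁶ before the log. The group-comparison t-test is
Student's pooled-variance form (Welch by flag), with p = 1 by convention for
two zero-variance samples with equal means.

## Discriminant analysis

Predictors are (T, CHbT, StO2, StMet), their squares and pairwise products
(14 columns; a `squares_only` flag gives the 8-column reading), z-standardized
with stored training statistics — T is in seconds (5 min to 72 h =
300–259 200 s) and would otherwise dominate the scatter matrices. CDA solves
B·v = λ·W·v via the symmetric generalized eigensolver, keeps the top
min(g−1, rank) axes scaled to unit pooled within-class variance
(vᵀWv = n−g), and fixes each axis's sign by its largest-magnitude
coefficient. Wilks' Λ = Π(1+λ_k)⁻¹ with Bartlett's χ² approximation; the
identity Λ = det(W)/det(W+B) is asserted. Classification is Euclidean
nearest-centroid in canonical space (where pooled within-class covariance is
white), ties toward the lowest class code; LOOCV refits the entire
expand→standardize→fit chain per fold. The one-vs-rest ROC scores each sample
by (min distance to any negative centroid) − (distance to the positive
centroid); tied scores are grouped so the trapezoid AUC equals the
Mann–Whitney statistic with midrank tie correction. Singular within-class
scatter falls back to ridge ε = 10⁻⁸·tr(W)/p.

## Pixel mapping

`classify_pixel_map` assembles (T, CHbT, StO2, StMet) per valid pixel — T is
the image's scalar acquisition time, an observation-level covariate — applies
the model's stored transform, projects, and assigns the nearest centroid.
No spatial smoothing or morphology is applied: heterogeneity in the label
image is treated as signal. Occupancy rates divide per-class counts by the
valid-pixel count inside the ROI (default 330×330 centered) and sum to 1 by
construction.

## Synthetic data

A `Scenario` fixes per-class, per-time means for (CHbT, StO2, StMet),
between-subject SDs, within-wound spatial SD and correlation length, sensor
noise (SD 0.005 reflectance units), image shape (128×128 default; the full
640×480 is configuration), and the 7-train/4-test subjects-per-class design
(7×3×4 = 84 training rows). The packaged defaults emulate, qualitatively, the
reported severity trajectories — hyperaemic CHbT rise with only transient
methemoglobin in the superficial burn; depressed CHbT and persistently rising
StMet in the deeper burns; melanin ≈ 0 for albino animals — but the source
protocol prints no numeric field values, so these are package defaults, not
measurements, and nothing in the tests claims agreement with real-animal
numbers. Spatial fields are Gaussian-kernel-smoothed white noise normalized by
the exact discrete kernel norm (so the per-pixel variance is right even when
the image is smaller than the correlation length), clipped to physiologic
bounds; species fields derive pixel-wise from the index fields, so
CHbT = CHbO+CHbR+CmetHb holds exactly by construction.

Cubes render truth through either forward mode: `mc_interp` (multilinear
interpolation of the Monte Carlo calibration spectra; raises outside the
calibration box) or `surrogate`, a modified Beer–Lambert map
A = µa(conc, λ)·ℓ + G with ℓ = 0.025 cm and G = 0.3. The surrogate is exactly
linear in the extinction spectra and hence exactly invertible by the unmixing
stage — it isolates plumbing and statistics (mapping, LOOCV, occupancy) from
Monte Carlo calibration error. ℓ was set so the darkest physiologic bands stay
comfortably above the sensor-noise floor while absorbances span ~0.1–1.5.
Bands outside the forward model's spectral support are filled by nearest-edge
extension; they carry no information and lie outside the regression window.

What passing synthetic tests shows: the pipeline's stages are internally
consistent, the inversion recovers known truth at its information limit, and
the discriminant mapping separates classes whose features are separated. What
it cannot show: that real burn wounds follow the scenario's trajectories, that
the two-layer skin model matches rat skin, or that real classification rates
match the synthetic ones.

## Problem sizes and tolerances

Default test/acceptance budgets: 20 000 base photons per calibration tier
(×2/4/10/25 by tier), 600-point grid, 14 bands; independent probe spectra are
simulated band-adaptively to an absorbance SE target (0.001 for the
whole-blood anchor), re-running a band with a photon count scaled from its
first-pass SE (strongly absorbed bands are cheap per photon, so this is
affordable). Monte Carlo equality checks use 3–3.5σ windows; exact algebraic
identities use 10⁻⁸–10⁻¹² depending on conditioning (the Rayleigh-quotient
check is relative, as separable clusters push eigenvalues to ~10⁷).
Stochastic suite checks run under fixed seeds and are therefore deterministic
in regression testing.

## Known limitations

- Single scattering spectrum: the calibration assumes one dermis power law;
  scattering variation between subjects/sites maps into concentration error.
- No depth resolution: the 550–680 nm window integrates over the light
  sampling depth, which itself varies with absorption.
- The empirical formulas are a global polynomial; accuracy is best inside the
  physiologic box and degrades toward its corners.
- The default scenario is a qualitative emulation; no claim of numerical
  agreement with any real dataset is made or tested.
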