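# burnhsi

Hyperspectral burn-depth imaging: Monte-Carlo-calibrated chromophore unmixing
and canonical discriminant mapping of burn severity.

## The problem

Early burn care hinges on knowing how deep a wound goes: superficial dermal
burns heal under dressings, while deep dermal and full-thickness burns need
excision and grafting. Visual assessment is unreliable, but burn depth leaves
a spectroscopic signature in the skin's hemodynamics — total hemoglobin
(CHbT), oxygen saturation (StO2) and, distinctively, methemoglobin (StMet),
the oxidized hemoglobin species that accumulates in thermally injured tissue.

`burnhsi` implements a complete pipeline from visible-range hyperspectral
reflectance cubes (400–1000 nm at 10 nm, 640×480 px, ~51 µm pitch) to
pixel-wise burn-severity maps:

1. **Reflectance → absorbance** (`burnhsi.spectra`). Raw cubes are ratioed
   against a 99%-reflectance white standard; A(λ) = −log₁₀R.
2. **Chromophore unmixing** (`burnhsi.unmixing`). Per pixel, A(λ) over
   550–680 nm is regressed on the molar extinction spectra of oxy-, deoxy-
   and met-hemoglobin, the melanin absorption spectrum, and an intercept:

   A(λ) ≈ a₁ε_HbO(λ) + a₂ε_HbR(λ) + a₃ε_metHb(λ) + a₄µ_mel(λ) + a₀.

3. **Monte Carlo calibration** (`burnhsi.montecarlo`, `burnhsi.forward_model`).
   The regression coefficients are not concentrations — photon path lengths in
   tissue depend on the very absorption being estimated. A layered-tissue
   photon-transport simulation (MCML-style: Henyey–Greenstein scattering,
   Fresnel boundaries, Russian roulette) of a two-layer skin model generates
   spectra at known concentrations; polynomial *empirical formulas* fitted on
   that grid invert coefficients → (Cm, CHbO, CHbR, CmetHb) at imaging speed.
   The indices follow as CHbT = CHbO+CHbR+CmetHb, StO2 = 100·CHbO/CHbT,
   StMet = 100·CmetHb/CHbT, with CHbT = 100 vol.% ≡ whole blood at 150 g/L
   hemoglobin.
4. **Canonical discriminant analysis** (`burnhsi.cda`). Observations
   (T, CHbT, StO2, StMet) with their second-order terms (14 predictors)
   discriminate three scald-burn severities (70 °C/78 °C/98 °C, coded 1/2/3);
   Wilks' Λ, leave-one-out cross-validation and one-vs-rest ROC/AUC summarize
   separation.
5. **Burn-depth mapping** (`burnhsi.burn_mapping`). The discriminant equations
   applied to every pixel of the index maps yield canonical scores (z₁, z₂);
   nearest-centroid labels produce a severity image and per-class occupancy
   rates over the 330×330 px analysis ROI.

No animal dataset ships with the package; `burnhsi.synthetic` generates
ground-truthed sample tables, spatially heterogeneous wound fields, and noisy
cubes through either the Monte-Carlo forward model or an exactly invertible
Beer–Lambert surrogate, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from burnhsi.montecarlo import MCConfig
from burnhsi.forward_model import (build_calibration_dataset,
                                   fit_empirical_formulas)
from burnhsi.spectra import (absorbance_from_reflectance, compute_reflectance,
                             load_extinction_library, ROI)
from burnhsi.synthetic import (default_scenario, generate_concentration_fields,
                               generate_hyperspectral_cube)
from burnhsi.unmixing import estimate_concentration_maps, roi_statistics

# Monte Carlo calibration of the inversion (minutes; reusable via to_json);
# the imaging profile regularizes for noisy per-pixel estimation
dataset = build_calibration_dataset(config=MCConfig(n_photons=20_000, seed=1))
formulas = fit_empirical_formulas(dataset, profile="imaging")

# a synthetic deep-dermal wound, 24 h post-burn, rendered to a noisy cube
scenario = default_scenario()
bundle = generate_concentration_fields(scenario, class_code=2, time_index=1, seed=7)
raw, white = generate_hyperspectral_cube(bundle, mode="mc_interp", seed=8,
                                         interpolator=dataset.interpolator())

# reflectance -> absorbance -> per-pixel concentration maps
library = load_extinction_library()
absorb = absorbance_from_reflectance(compute_reflectance(raw, white))
maps = estimate_concentration_maps(absorb, library, formulas)
roi = ROI.centered(maps.shape, size=96)
for name in ("chbt", "sto2", "stmet"):
    s = roi_statistics(maps[name], roi)
    print(f"{name:5s}  {s['mean']:6.2f} +- {s['sd']:5.2f}   (n={s['n']})")
```

prints (seed 1; means ± SD over the ROI)

```
chbt     8.24 +-  3.93   (n=9216)
sto2    33.76 +-  8.37   (n=9216)
stmet   16.91 +- 11.47   (n=9216)
```

against pixel-exact ground truth CHbT = 5.8 vol.%, StO2 = 34.4%,
StMet = 14.7%: the wound's depressed perfusion, intermediate oxygenation and
elevated methemoglobin are recovered pixel-wise from the noisy cube (the
per-pixel SDs reflect sensor noise plus true spatial heterogeneity, and CHbT
carries a small positive bias at low perfusion from the zero-clamp on species
estimates — see `docs/methods.md`). Feeding `maps` to `burnhsi.cda.fit_cda`
(via a sample table) and `burnhsi.burn_mapping.classify_pixel_map` yields the
severity label image and occupancy rates; the `burnhsi` command line
(`simulate`, `calibrate`, `unmix`, `cda-fit`, `cda-eval`, `map`, `pipeline`)
wraps the same calls.

## Layout

- `src/burnhsi/spectra.py` — wavelength grids, extinction library, cubes, ROI
- `src/burnhsi/montecarlo.py` — photon-transport kernels (direct + path-recording)
- `src/burnhsi/forward_model.py` — skin model, calibration grid, empirical formulas
- `src/burnhsi/unmixing.py` — per-pixel regression, index maps, ROI stats, t-test
- `src/burnhsi/cda.py` — discriminant model, Wilks' Λ, LOOCV, ROC
- `src/burnhsi/burn_mapping.py` — label images, occupancy, rendering
- `src/burnhsi/synthetic.py` — scenario-driven ground-truthed data generators
- `src/burnhsi/io.py`, `src/burnhsi/cli.py` — ENVI/TIFF/CSV/JSON I/O and the CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
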