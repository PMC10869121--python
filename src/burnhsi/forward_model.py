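"""Forward optical model of burned skin and the empirical inversion formulas.

The tissue is modeled as two plane-parallel layers under air: a 100-um
epidermis whose absorption comes from melanin, above a semi-infinite dermis
whose absorption comes from blood (oxy-, deoxy- and met-hemoglobin) uniformly
distributed at a volume fraction CHbT, where CHbT = 100 vol.% corresponds to
whole blood with 150 g/L hemoglobin.  Scattering in both layers follows a
reduced-scattering power law mus'(lambda) = a * (lambda/500 nm)^-b with
Henyey-Greenstein anisotropy g.

Monte Carlo transport through this model generates a calibration dataset:
ground-truth concentration vectors mapped to the regression coefficients that
the spectral unmixing step recovers from the simulated absorbance spectra.
Polynomial "empirical formulas" fitted on that dataset invert new coefficient
vectors to concentration estimates at imaging speed.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .montecarlo import MCConfig, MCResult, run_transport, sample_pathlengths
from .spectra import ChromophoreLibrary, WavelengthGrid, load_extinction_library, unmixing_grid

__all__ = [
    "HB_GRAMS_PER_LITER", "HB_MOLAR_MASS", "HB_MOLARITY_WHOLE_BLOOD",
    "Concentrations", "SkinModel", "default_skin_model",
    "mua_from_concentrations", "simulate_diffuse_reflectance",
    "CalibrationDataset", "build_calibration_dataset", "default_grid_spec",
    "simulate_reflectance_spectrum",
    "EmpiricalFormulaSet", "fit_empirical_formulas", "apply_empirical_formulas",
    "ReflectanceInterpolator",
]

#: Whole blood carries 150 g/L hemoglobin; with the 64,500 g/mol tetramer
#: molar mass this fixes the hemoglobin molarity of 100 vol.% blood.
HB_GRAMS_PER_LITER = 150.0
HB_MOLAR_MASS = 64_500.0
HB_MOLARITY_WHOLE_BLOOD = HB_GRAMS_PER_LITER / HB_MOLAR_MASS  # mol/L

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class Concentrations:
    """Chromophore volume concentrations in vol.%.

    ``cm`` is epidermal melanin; ``chbo``/``chbr``/``cmethb`` are dermal blood
    fractions carrying oxy-, deoxy- and met-hemoglobin.  ``validate_physical``
    additionally enforces the blood-budget constraint sum <= 100 vol.%.
    """

    cm: float = 0.0
    chbo: float = 0.0
    chbr: float = 0.0
    cmethb: float = 0.0

    def __post_init__(self):
        if min(self.cm, self.chbo, self.chbr, self.cmethb) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def chbt(self) -> float:
        return self.chbo + self.chbr + self.cmethb

    def validate_physical(self):
        if self.chbt > 100.0 + 1e-9:
            raise ValueError(f"total hemoglobin {self.chbt} vol.% exceeds 100")

    def as_array(self) -> np.ndarray:
        return np.array([self.cm, self.chbo, self.chbr, self.cmethb])


@dataclass(frozen=True)
class SkinModel:
    """Two-layer skin optical model (epidermis over semi-infinite dermis)."""

    epidermis_thickness_cm: float = 0.01
    n_epidermis: float = 1.4
    n_dermis: float = 1.4
    g: float = 0.9
    musp_500: float = 45.3          # reduced scattering at 500 nm, cm^-1
    scatter_power: float = 1.292
    mua_background: float = 0.2     # bloodless-tissue baseline absorption, cm^-1

    def musp(self, wavelength_nm) -> np.ndarray:
        lam = np.asarray(wavelength_nm, dtype=float)
        return self.musp_500 * (lam / 500.0) ** (-self.scatter_power)

    def mus(self, wavelength_nm) -> np.ndarray:
        return self.musp(wavelength_nm) / (1.0 - self.g)


def default_skin_model() -> SkinModel:
    return SkinModel()


def mua_from_concentrations(conc: Concentrations, wavelength_nm,
                            library: ChromophoreLibrary,
                            model: SkinModel | None = None):
    """Per-layer absorption coefficients (cm^-1) at the requested wavelengths.

    Dermal absorption is the Beer-Lambert sum over hemoglobin species,
    mua = ln(10) * c_blood * sum_i (C_i/100) * eps_i(lambda), with c_blood the
    hemoglobin molarity of whole blood; epidermal absorption is the melanin
    fraction times the pure-melanin absorption spectrum.  A constant baseline
    (bloodless tissue) is added to both layers.

    Returns ``(mua_epidermis, mua_dermis)`` arrays aligned with the library
    grid entries at ``wavelength_nm``.
    """
    if model is None:
        model = default_skin_model()
    lam = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
    idx = np.searchsorted(library.grid.values, lam)
    if np.any(idx >= len(library.grid)) or np.any(~np.isclose(library.grid.values[np.minimum(idx, len(library.grid) - 1)], lam)):
        raise ValueError("wavelengths must be nodes of the library grid")
    eps_hbo = library.eps_hbo[idx]
    eps_hbr = library.eps_hbr[idx]
    eps_met = library.eps_methb[idx]
    mu_mel = library.mu_mel[idx]
    hb_sum = (conc.chbo * eps_hbo + conc.chbr * eps_hbr + conc.cmethb * eps_met) / 100.0
    mua_derm = _LN10 * HB_MOLARITY_WHOLE_BLOOD * hb_sum + model.mua_background
    mua_epi = (conc.cm / 100.0) * mu_mel + model.mua_background
    return mua_epi, mua_derm


def simulate_diffuse_reflectance(conc: Concentrations, wavelength_nm: float,
                                 config: MCConfig,
                                 library: ChromophoreLibrary | None = None,
                                 model: SkinModel | None = None) -> MCResult:
    """Direct Monte Carlo diffuse reflectance of the skin model at one wavelength."""
    if library is None:
        library = load_extinction_library()
    if model is None:
        model = default_skin_model()
    mua_epi, mua_derm = mua_from_concentrations(conc, wavelength_nm, library, model)
    mus = model.mus(wavelength_nm)
    return run_transport(
        mua=[float(mua_epi[0]), float(mua_derm[0])],
        mus=[float(mus), float(mus)],
        g=[model.g, model.g],
        n=[model.n_epidermis, model.n_dermis],
        thickness=[model.epidermis_thickness_cm, np.inf],
        config=config,
    )


def simulate_reflectance_spectrum(conc: Concentrations, grid: WavelengthGrid,
                                  config: MCConfig,
                                  library: ChromophoreLibrary | None = None,
                                  model: SkinModel | None = None,
                                  target_absorbance_se: float | None = None,
                                  max_photons: int = 2_000_000) -> np.ndarray:
    """Direct Monte Carlo Rd spectrum over a wavelength grid.

    With ``target_absorbance_se`` set, each band is re-run with a photon count
    scaled to bring the absorbance standard error sigma_Rd/(Rd ln 10) under
    the target (strongly absorbed bands need more photons for the same
    absorbance precision, but their short photon histories keep them cheap).
    Band seeds are config.seed + band index (+ an offset for the refinement
    pass).
    """
    if library is None:
        library = load_extinction_library(grid=grid)
    if model is None:
        model = default_skin_model()
    rd = np.empty(len(grid))
    for ib, lam in enumerate(grid.values):
        res = simulate_diffuse_reflectance(conc, lam, config.with_seed(config.seed + ib),
                                           library=library, model=model)
        if target_absorbance_se is not None and res.rd > 0:
            se_a = res.rd_se / (res.rd * _LN10)
            if se_a > target_absorbance_se:
                n_new = int(min(max_photons,
                                config.n_photons * (se_a / target_absorbance_se) ** 2))
                cfg = MCConfig(n_new, (config.seed + 10_000 + ib) % (2**31),
                               config.weight_threshold, config.survival_chance,
                               config.max_interactions)
                res = simulate_diffuse_reflectance(conc, lam, cfg,
                                                   library=library, model=model)
        rd[ib] = res.rd
    return rd


# ---------------------------------------------------------------------------
# Calibration dataset
# ---------------------------------------------------------------------------

def default_grid_spec() -> dict:
    """Default calibration grid (vol.%), spanning albino-to-pigmented melanin
    and bloodless-to-whole-blood perfusion so the inversion formulas cover the
    whole-blood definitional anchor (CHbT = 100).  The axes are dense at low
    concentrations — the diffuse-reflectance surface is strongly convex there,
    and coarse cells would make multilinearly interpolated spectra unphysical
    mixtures (grid density costs no additional photon transport, only
    reweighting).  Tensor corners whose species sum exceeds 100 vol.% are
    retained as interpolation scaffolding."""
    return {
        "cm": [0.0, 5.0, 10.0],
        "chbo": [0.0, 2.0, 4.0, 7.0, 10.0, 15.0, 20.0, 35.0, 50.0, 70.0, 85.0, 100.0],
        "chbr": [0.0, 2.0, 4.0, 7.0, 10.0, 15.0, 20.0, 30.0, 45.0],
        "cmethb": [0.0, 1.0, 2.0, 4.0, 7.0, 10.0, 15.0, 20.0, 30.0],
    }


@dataclass
class CalibrationDataset:
    """(ground truth, simulated spectrum, regression coefficients) records on a
    tensor-product concentration grid."""

    axes: dict                    # axis name -> list of grid values (vol.%)
    grid: WavelengthGrid
    truth: np.ndarray             # (N, 4): cm, chbo, chbr, cmethb
    reflectance: np.ndarray       # (N, n_bands)
    coefficients: np.ndarray      # (N, 5): a_hbo, a_hbr, a_met, a_mel, a_0
    r_squared: np.ndarray         # (N,)
    excluded: np.ndarray          # (N,) bool, records with non-positive Rd
    provenance: dict = field(default_factory=dict)

    AXIS_NAMES = ("cm", "chbo", "chbr", "cmethb")

    def __post_init__(self):
        n = self.truth.shape[0]
        assert self.reflectance.shape[0] == self.coefficients.shape[0] == n

    @property
    def n_records(self) -> int:
        return int(self.truth.shape[0])

    def interpolator(self) -> "ReflectanceInterpolator":
        return ReflectanceInterpolator(self)

    def spectra_to_csv(self, path):
        """Dump truth + simulated Rd spectra as one delimited-text table."""
        import pandas as pd
        cols = {n: self.truth[:, i] for i, n in enumerate(self.AXIS_NAMES)}
        for ib, lam in enumerate(self.grid.values):
            cols[f"rd_{lam:g}nm"] = self.reflectance[:, ib]
        pd.DataFrame(cols).to_csv(path, index=False)
        return path

    def to_json(self, path):
        obj = {
            "axes": {k: list(map(float, v)) for k, v in self.axes.items()},
            "wavelengths_nm": self.grid.values.tolist(),
            "truth": self.truth.tolist(),
            "reflectance": self.reflectance.tolist(),
            "coefficients": self.coefficients.tolist(),
            "r_squared": self.r_squared.tolist(),
            "excluded": self.excluded.astype(int).tolist(),
            "provenance": self.provenance,
        }
        with open(path, "w") as f:
            json.dump(obj, f)

    @classmethod
    def from_json(cls, path) -> "CalibrationDataset":
        with open(path) as f:
            obj = json.load(f)
        return cls(
            axes=obj["axes"],
            grid=WavelengthGrid(np.array(obj["wavelengths_nm"])),
            truth=np.array(obj["truth"]),
            reflectance=np.array(obj["reflectance"]),
            coefficients=np.array(obj["coefficients"]),
            r_squared=np.array(obj["r_squared"]),
            excluded=np.array(obj["excluded"], dtype=bool),
            provenance=obj.get("provenance", {}),
        )


def build_calibration_dataset(grid_spec: dict | None = None,
                              model: SkinModel | None = None,
                              grid: WavelengthGrid | None = None,
                              config: MCConfig | None = None,
                              library: ChromophoreLibrary | None = None,
                              method: str = "pathlength",
                              tiers=((60.0, 2, 0.0), (12.0, 4, 0.7),
                                     (4.0, 10, 2.0), (1.3, 25, 18.0))
                              ) -> CalibrationDataset:
    """Simulate the concentration grid and unmix each simulated spectrum.

    ``method='pathlength'`` (default) runs zero-absorption transport per
    wavelength and obtains every grid point's Rd by absorption reweighting of
    the recorded photon paths.  ``tiers`` is a sequence of (dermal path cap in
    cm, photon multiplier, lower dermal-mua bound in cm^-1): a tier is valid
    for the grid points whose dermal absorption exceeds its bound, where the
    histories its cap discards would have carried negligible attenuation
    weight (cap * mua_lo >= ~8, with the dermal background absorption
    covering the always-valid first tier), so strongly absorbed bands can
    afford many more photons.  Every valid tier's estimate is combined by
    inverse-variance weighting, which keeps the absorbance noise roughly
    uniform across the grid at fixed cost and — because the weights vary
    continuously with absorption — leaves no sampling discontinuities along
    the concentration axes for the downstream polynomial fit to amplify.  The
    photon budget of tier k is ``config.n_photons`` times its multiplier.

    ``method='direct'`` runs an independent transport simulation per
    (grid point, wavelength) with seed = base seed + record index * n_bands +
    band index; it is the slower reference path.
    """
    from .unmixing import fit_absorbance_spectrum  # late import; no cycle at module load

    grid_spec = dict(grid_spec or default_grid_spec())
    model = model or default_skin_model()
    grid = grid or unmixing_grid()
    config = config or MCConfig()
    library = library or load_extinction_library(grid=grid)
    if not np.array_equal(library.grid.values, grid.values):
        library = library.resample(grid)

    axes_vals = [np.asarray(grid_spec[k], dtype=float) for k in CalibrationDataset.AXIS_NAMES]
    points = np.array(list(itertools.product(*axes_vals)))   # (N, 4)
    n_records = points.shape[0]
    n_bands = len(grid)
    lam = grid.values
    mus = model.mus(lam)

    rd = np.empty((n_records, n_bands))
    if method == "pathlength":
        layers = dict(g=[model.g, model.g],
                      n=[model.n_epidermis, model.n_dermis],
                      thickness=[model.epidermis_thickness_cm, np.inf])
        for ib in range(n_bands):
            mua = np.empty((n_records, 2))
            for i in range(n_records):
                conc = Concentrations(*points[i])
                e, d = mua_from_concentrations(conc, lam[ib], library, model)
                mua[i] = (e[0], d[0])
            num = np.zeros(n_records)
            den = np.zeros(n_records)
            for it, (cap, factor, mua_lo) in enumerate(tiers):
                sel = mua[:, 1] >= mua_lo
                if not sel.any():
                    continue
                # correlated sampling: one random stream per tier, shared by
                # all bands, so the Monte Carlo error of the Rd surface is
                # common-mode (smooth) across wavelength instead of band-to-
                # band jitter that the downstream regression cannot absorb
                ps = sample_pathlengths(
                    mus=[mus[ib], mus[ib]],
                    config=MCConfig(config.n_photons * factor,
                                    (config.seed + it) % (2**31),
                                    config.weight_threshold, config.survival_chance,
                                    config.max_interactions),
                    layer_caps=[60.0, cap], **layers)
                est, se = ps.reflectance_se(mua[sel])
                w = 1.0 / np.maximum(se, 1e-12) ** 2
                num[sel] += w * est
                den[sel] += w
            rd[:, ib] = num / den
    elif method == "direct":
        for i in range(n_records):
            conc = Concentrations(*points[i])
            for ib in range(n_bands):
                res = simulate_diffuse_reflectance(
                    conc, lam[ib],
                    MCConfig(n_photons=config.n_photons,
                             seed=(config.seed + i * n_bands + ib) % (2**31),
                             weight_threshold=config.weight_threshold,
                             survival_chance=config.survival_chance,
                             max_interactions=config.max_interactions),
                    library=library, model=model)
                rd[i, ib] = res.rd
    else:
        raise ValueError(f"unknown method {method!r}")

    excluded = np.any(rd <= 0.0, axis=1)
    coeffs = np.full((n_records, 5), np.nan)
    r2 = np.full(n_records, np.nan)
    for i in range(n_records):
        if excluded[i]:
            continue
        a = -np.log10(rd[i])
        res = fit_absorbance_spectrum(a, library, window=(lam[0], lam[-1]))
        coeffs[i] = res.as_array()
        r2[i] = res.r_squared

    return CalibrationDataset(
        axes={k: v.tolist() for k, v in zip(CalibrationDataset.AXIS_NAMES, axes_vals)},
        grid=grid, truth=points, reflectance=rd, coefficients=coeffs,
        r_squared=r2, excluded=excluded,
        provenance={
            "method": method, "n_photons": config.n_photons, "seed": config.seed,
            "weight_threshold": config.weight_threshold,
            "survival_chance": config.survival_chance,
            "tiers": [list(t) for t in tiers],
            "model": asdict(model),
            "library": {"source": library.source, "version": library.version},
            "n_excluded": int(excluded.sum()),
        },
    )


class ReflectanceInterpolator:
    """Multilinear interpolation of simulated Rd spectra over the
    concentration grid (the ``mc_interp`` forward mode for synthetic cubes)."""

    def __init__(self, dataset: CalibrationDataset):
        from scipy.interpolate import RegularGridInterpolator

        if dataset.excluded.any():
            raise ValueError("cannot interpolate a dataset with excluded records")
        axes = [np.asarray(dataset.axes[k], dtype=float) for k in CalibrationDataset.AXIS_NAMES]
        shape = tuple(len(a) for a in axes) + (len(dataset.grid),)
        tensor = dataset.reflectance.reshape(shape)
        self._interp = RegularGridInterpolator(axes, tensor, bounds_error=True)
        self.grid = dataset.grid
        self.lo = np.array([a[0] for a in axes])
        self.hi = np.array([a[-1] for a in axes])

    def __call__(self, concentrations) -> np.ndarray:
        """Rd spectra for points (..., 4) ordered (cm, chbo, chbr, cmethb)."""
        pts = np.asarray(concentrations, dtype=float)
        if np.any(pts < self.lo) or np.any(pts > self.hi):
            raise ValueError("concentration outside the calibration grid box")
        return self._interp(pts)


# ---------------------------------------------------------------------------
# Empirical formulas
# ---------------------------------------------------------------------------

_COEFF_NAMES = ("a_hbo", "a_hbr", "a_met", "a_mel", "a_0")


def _poly_exponents(n_vars: int, degree: int):
    """All monomial exponent tuples with total degree <= degree (constant first)."""
    exps = []
    for total in range(degree + 1):
        for combo in itertools.combinations_with_replacement(range(n_vars), total):
            e = [0] * n_vars
            for v in combo:
                e[v] += 1
            exps.append(tuple(e))
    return exps


def _poly_design(x: np.ndarray, exponents) -> np.ndarray:
    cols = [np.prod(x ** np.array(e), axis=-1) for e in exponents]
    return np.stack(cols, axis=-1)


@dataclass
class EmpiricalFormulaSet:
    """Polynomial maps from the five regression coefficients to concentrations.

    One polynomial per chromophore, fitted on the calibration dataset.  The
    training-domain bounding box (in coefficient space) drives the
    extrapolation flag; negative evaluations are clamped to zero with a clamp
    flag.
    """

    degree: int
    exponents: list
    coef: dict                     # chromophore -> (n_terms,) array
    scale_mu: np.ndarray           # (5,) input standardization (conditioning)
    scale_sd: np.ndarray
    bbox_lo: np.ndarray            # (5,) over (a_hbo, a_hbr, a_met, a_mel, a_0)
    bbox_hi: np.ndarray
    heldout_rmse: dict             # chromophore -> float
    provenance: dict = field(default_factory=dict)

    TARGETS = ("cm", "chbo", "chbr", "cmethb")

    def evaluate(self, coefficients):
        """Concentration estimates for coefficient vectors (..., 5).

        Returns ``(values, clamped, extrapolated)``: values is (..., 4) ordered
        (cm, chbo, chbr, cmethb); the flags are boolean arrays over the leading
        shape.
        """
        x = np.asarray(coefficients, dtype=float)
        if x.shape[-1] != 5:
            raise ValueError("coefficient vectors must have 5 entries")
        design = _poly_design((x - self.scale_mu) / self.scale_sd, self.exponents)
        vals = np.stack([design @ self.coef[t] for t in self.TARGETS], axis=-1)
        extrapolated = np.any((x < self.bbox_lo) | (x > self.bbox_hi), axis=-1)
        clamped = np.any(vals < 0, axis=-1)
        vals = np.maximum(vals, 0.0)
        return vals, clamped, extrapolated

    def to_json(self, path):
        obj = {
            "degree": self.degree,
            "exponents": [list(e) for e in self.exponents],
            "scale_mu": self.scale_mu.tolist(),
            "scale_sd": self.scale_sd.tolist(),
            "coef": {k: v.tolist() for k, v in self.coef.items()},
            "bbox_lo": self.bbox_lo.tolist(),
            "bbox_hi": self.bbox_hi.tolist(),
            "heldout_rmse": self.heldout_rmse,
            "provenance": self.provenance,
        }
        with open(path, "w") as f:
            json.dump(obj, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "EmpiricalFormulaSet":
        with open(path) as f:
            obj = json.load(f)
        return cls(
            degree=obj["degree"],
            exponents=[tuple(e) for e in obj["exponents"]],
            scale_mu=np.array(obj["scale_mu"]),
            scale_sd=np.array(obj["scale_sd"]),
            coef={k: np.array(v) for k, v in obj["coef"].items()},
            bbox_lo=np.array(obj["bbox_lo"]),
            bbox_hi=np.array(obj["bbox_hi"]),
            heldout_rmse=obj["heldout_rmse"],
            provenance=obj.get("provenance", {}),
        )


class FormulaFitError(RuntimeError):
    pass


#: Named formula-fit profiles.  ``full-range`` spans bloodless to whole blood
#: (needed to invert high-perfusion spectra, e.g. the CHbT = 100 anchor) with
#: light noise regularization suited to high-precision single spectra;
#: ``imaging`` restricts the fit to the physiologic imaging range and
#: regularizes at the per-pixel sensor-noise level, trading high-end reach for
#: markedly better accuracy on noisy per-pixel map estimation.
FIT_PROFILES = {
    "full-range": {"degree": 3, "max_total_hb": 130.0, "augment_sigma": 0.001},
    "imaging": {"degree": 3, "max_total_hb": 35.0, "augment_sigma": 0.003},
}


def fit_empirical_formulas(dataset: CalibrationDataset, degree: int = 3,
                           max_total_hb: float = 130.0,
                           n_augment: int = 30,
                           augment_sigma: float = 0.001,
                           library: ChromophoreLibrary | None = None,
                           profile: str | None = None) -> EmpiricalFormulaSet:
    """Least-squares polynomial fit per chromophore from regression
    coefficients to true concentrations.

    Only records with total hemoglobin <= ``max_total_hb`` vol.% enter the
    fit: tensor-product grid corners far beyond whole blood exist solely as
    interpolation scaffolding and their extreme nonlinearity degrades the
    global polynomial (the margin above 100 vol.% stabilizes the fit at the
    whole-blood boundary).  Each record is augmented with ``n_augment``
    replicates whose absorbance spectra carry i.i.d. Gaussian noise of SD
    ``augment_sigma`` before re-projection through the unmixing operator; the
    regression predictors are nearly collinear over the 550-680 nm window, so
    without this the formulas amplify measurement noise along the
    ill-conditioned coefficient directions.  Coefficient inputs are
    standardized before the polynomial expansion for conditioning.

    Held-out RMSE comes from an every-5th-record split after a deterministic
    shuffle (a plain stride aliases with the grid axes); the final
    coefficients use all records.  Requires at least 3x more base records
    than polynomial terms.
    """
    from .unmixing import _window_design  # shared OLS design; no cycle at module load

    if profile is not None:
        p = FIT_PROFILES[profile]
        degree = p["degree"]
        max_total_hb = p["max_total_hb"]
        augment_sigma = p["augment_sigma"]
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    keep = ~dataset.excluded & (dataset.truth[:, 1:].sum(axis=1) <= max_total_hb)
    x = dataset.coefficients[keep]
    y = dataset.truth[keep]
    exponents = _poly_exponents(5, degree)
    n_terms = len(exponents)
    if x.shape[0] < 3 * n_terms:
        raise FormulaFitError(
            f"{x.shape[0]} records < 3 x {n_terms} polynomial terms; enlarge the grid")

    if n_augment > 0:
        library = library or load_extinction_library(grid=dataset.grid)
        _, design_x = _window_design(library, (dataset.grid.values[0], dataset.grid.values[-1]))
        proj = np.linalg.pinv(design_x)             # (5, n_bands)
        rng = np.random.default_rng(dataset.provenance.get("seed", 0) or 0)
        noise = rng.normal(0.0, augment_sigma,
                           (n_augment, x.shape[0], design_x.shape[0]))
        x_fit = np.concatenate([x[None]] + [x[None] + noise[k] @ proj.T
                                            for k in range(n_augment)])
        x_fit = x_fit.reshape(-1, 5)
        y_fit = np.tile(y, (n_augment + 1, 1))
    else:
        x_fit, y_fit = x, y

    # standardize the coefficient inputs: the raw columns span orders of
    # magnitude and an unscaled cubic design is numerically singular
    mu = x_fit.mean(axis=0)
    sd = x_fit.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    design = _poly_design((x_fit - mu) / sd, exponents)

    rank = np.linalg.matrix_rank(design)
    if rank < n_terms:
        # name the trailing terms that QR finds dependent
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [exponents[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise FormulaFitError(f"rank-deficient polynomial design; collinear terms: {bad}")

    # held-out split over base records, replicated onto their augmentations
    perm = np.random.default_rng(x.shape[0]).permutation(x.shape[0])
    hold_base = np.zeros(x.shape[0], dtype=bool)
    hold_base[perm[::5]] = True
    hold = np.tile(hold_base, x_fit.shape[0] // x.shape[0])
    coef = {}
    rmse = {}
    for j, target in enumerate(EmpiricalFormulaSet.TARGETS):
        b_split, *_ = np.linalg.lstsq(design[~hold], y_fit[~hold, j], rcond=None)
        resid = design[hold] @ b_split - y_fit[hold, j]
        rmse[target] = float(np.sqrt(np.mean(resid**2)))
        b_full, *_ = np.linalg.lstsq(design, y_fit[:, j], rcond=None)
        coef[target] = b_full

    return EmpiricalFormulaSet(
        degree=degree, exponents=exponents, coef=coef, scale_mu=mu, scale_sd=sd,
        bbox_lo=x_fit.min(axis=0), bbox_hi=x_fit.max(axis=0),
        heldout_rmse=rmse,
        provenance={"n_records": int(x.shape[0]), "max_total_hb": max_total_hb,
                    "n_augment": n_augment, "augment_sigma": augment_sigma,
                    "profile": profile, **dataset.provenance},
    )


def apply_empirical_formulas(formulas: EmpiricalFormulaSet, coefficients):
    """Evaluate the formulas for one coefficient vector; returns
    ``(Concentrations, clamped flag, extrapolation flag)``."""
    vals, clamped, extrap = formulas.evaluate(np.asarray(coefficients, dtype=float))
    c = Concentrations(cm=float(vals[..., 0]), chbo=float(vals[..., 1]),
                       chbr=float(vals[..., 2]), cmethb=float(vals[..., 3]))
    return c, bool(clamped), bool(extrap)
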