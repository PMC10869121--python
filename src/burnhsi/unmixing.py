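"""Chromophore unmixing by multiple regression of absorbance on extinction spectra.

Per spectrum (or per pixel), absorbance A(lambda) over the 550-680 nm window is
regressed on the molar extinction spectra of oxy-, deoxy- and met-hemoglobin,
the melanin absorption spectrum, and an intercept that absorbs the
wavelength-flat part of scattering loss.  The regression coefficients feed the
Monte-Carlo-calibrated empirical formulas to yield concentration maps, from
which the hemoglobin indices CHbT = CHbO + CHbR + CmetHb, StO2 = 100*CHbO/CHbT
and StMet = 100*CmetHb/CHbT follow pixel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spectra import AbsorbanceCube, ChromophoreLibrary, ROI

__all__ = [
    "RegressionResult", "ParameterMaps", "fit_absorbance_spectrum",
    "estimate_concentration_maps", "hemoglobin_indices", "roi_statistics",
    "unpaired_t_test", "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = (550.0, 680.0)
MAP_NAMES = ("cm", "chbo", "chbr", "cmethb", "chbt", "sto2", "stmet", "r2")


@dataclass(frozen=True)
class RegressionResult:
    """OLS coefficients of one absorbance spectrum on the chromophore library."""

    a_hbo: float
    a_hbr: float
    a_met: float
    a_mel: float
    a_0: float
    r_squared: float
    residuals: np.ndarray

    def as_array(self) -> np.ndarray:
        return np.array([self.a_hbo, self.a_hbr, self.a_met, self.a_mel, self.a_0])


def _window_design(library: ChromophoreLibrary, window):
    lo, hi = window
    sel = library.grid.window(lo, hi)
    if sel.sum() < 6:
        raise ValueError(f"need >= 6 bands inside window {window}, have {int(sel.sum())}")
    sub = library.subset(lo, hi)
    x = sub.design_matrix(intercept=True)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("collinear extinction predictors on this grid")
    return sel, x


def _ols(x: np.ndarray, y: np.ndarray):
    """Least squares of y (n_bands, m) on x (n_bands, 5); returns (beta, r2, resid)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    resid = y - fitted
    ss_res = np.sum(resid**2, axis=0)
    ss_tot = np.sum((y - y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return beta, np.clip(r2, 0.0, 1.0), resid


def fit_absorbance_spectrum(absorbance, library: ChromophoreLibrary,
                            window=DEFAULT_WINDOW) -> RegressionResult:
    """Fit one absorbance spectrum (aligned with the library grid) by OLS.

    Only bands inside ``window`` (inclusive endpoints) enter the regression.
    R^2 is computed against the intercept-only model and, with an intercept in
    the design, lies in [0, 1].
    """
    a = np.asarray(absorbance, dtype=float)
    if a.shape != (len(library.grid),):
        raise ValueError("absorbance must align with the library grid")
    sel, x = _window_design(library, window)
    y = a[sel]
    beta, r2, resid = _ols(x, y[:, None])
    b = beta[:, 0]
    return RegressionResult(a_hbo=b[0], a_hbr=b[1], a_met=b[2], a_mel=b[3],
                            a_0=b[4], r_squared=float(r2[0]), residuals=resid[:, 0])


def hemoglobin_indices(chbo, chbr, cmethb):
    """Hemoglobin indices from species concentrations (vol.%).

    Returns ``(chbt, sto2, stmet, undefined)``; where CHbT = 0 the saturations
    are reported as 0 with the ``undefined`` flag set.  Accepts scalars or
    arrays.
    """
    chbo = np.asarray(chbo, dtype=float)
    chbr = np.asarray(chbr, dtype=float)
    cmethb = np.asarray(cmethb, dtype=float)
    if np.any(chbo < 0) or np.any(chbr < 0) or np.any(cmethb < 0):
        raise ValueError("concentrations must be non-negative")
    chbt = chbo + chbr + cmethb
    undefined = chbt == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        sto2 = np.where(undefined, 0.0, 100.0 * chbo / np.where(undefined, 1.0, chbt))
        stmet = np.where(undefined, 0.0, 100.0 * cmethb / np.where(undefined, 1.0, chbt))
    # guard the one-ulp overshoot of 100 * x / x
    return chbt, np.minimum(sto2, 100.0), np.minimum(stmet, 100.0), undefined


@dataclass
class ParameterMaps:
    """Per-pixel chromophore and hemoglobin-index rasters sharing one mask.

    ``maps`` holds rasters keyed by ``cm, chbo, chbr, cmethb, chbt, sto2,
    stmet, r2`` (vol.%, vol.%, vol.%, vol.%, vol.%, %, %, unitless); masked
    pixels carry NaN.  ``undefined`` marks valid pixels whose CHbT is zero,
    where the saturations are 0 by convention; ``clamped``/``extrapolated``
    carry the inversion flags.
    """

    maps: dict
    mask: np.ndarray
    undefined: np.ndarray
    clamped: np.ndarray
    extrapolated: np.ndarray
    window: tuple
    provenance: dict

    def __getitem__(self, key) -> np.ndarray:
        return self.maps[key]

    @property
    def shape(self):
        return self.mask.shape


def estimate_concentration_maps(cube: AbsorbanceCube, library: ChromophoreLibrary,
                                formulas, window=DEFAULT_WINDOW) -> ParameterMaps:
    """Per-pixel unmixing of an absorbance cube into parameter maps.

    Runs the window OLS on every valid pixel (vectorized over pixels), then the
    empirical-formula inversion, then the hemoglobin indices.  Masked pixels
    propagate as NaN in every output raster.
    """
    if cube.grid.values[0] > window[0] or cube.grid.values[-1] < window[1]:
        raise ValueError("cube grid does not cover the unmixing window")
    lib = library if np.array_equal(library.grid.values, cube.grid.values) \
        else library.subset(cube.grid.values[0], cube.grid.values[-1])
    if not np.array_equal(lib.grid.values, cube.grid.values):
        raise ValueError("library does not cover the cube grid")
    sel, x = _window_design(lib, window)

    rows, cols, _ = cube.data.shape
    flat = cube.data.reshape(rows * cols, -1)[:, sel]
    valid = cube.mask.ravel() & np.all(np.isfinite(flat), axis=1)

    coeffs = np.full((rows * cols, 5), np.nan)
    r2 = np.full(rows * cols, np.nan)
    if valid.any():
        beta, r2v, _ = _ols(x, flat[valid].T)
        coeffs[valid] = beta.T
        r2[valid] = r2v

    conc = np.full((rows * cols, 4), np.nan)
    clamped = np.zeros(rows * cols, dtype=bool)
    extrap = np.zeros(rows * cols, dtype=bool)
    if valid.any():
        vals, cl, ex = formulas.evaluate(coeffs[valid])
        conc[valid] = vals
        clamped[valid] = cl
        extrap[valid] = ex

    chbt = np.full(rows * cols, np.nan)
    sto2 = np.full(rows * cols, np.nan)
    stmet = np.full(rows * cols, np.nan)
    undefined = np.zeros(rows * cols, dtype=bool)
    if valid.any():
        t, s, m, u = hemoglobin_indices(conc[valid, 1], conc[valid, 2], conc[valid, 3])
        chbt[valid] = t
        sto2[valid] = s
        stmet[valid] = m
        undefined[valid] = u

    shape = (rows, cols)
    maps = {
        "cm": conc[:, 0].reshape(shape), "chbo": conc[:, 1].reshape(shape),
        "chbr": conc[:, 2].reshape(shape), "cmethb": conc[:, 3].reshape(shape),
        "chbt": chbt.reshape(shape), "sto2": sto2.reshape(shape),
        "stmet": stmet.reshape(shape), "r2": r2.reshape(shape),
    }
    return ParameterMaps(
        maps=maps, mask=(valid.reshape(shape) & cube.mask),
        undefined=undefined.reshape(shape), clamped=clamped.reshape(shape),
        extrapolated=extrap.reshape(shape), window=tuple(window),
        provenance={"library": {"source": lib.source, "version": lib.version}},
    )


def roi_statistics(map_2d, roi: ROI, mask=None):
    """Mean, sample SD (n-1 denominator) and valid-pixel count over an ROI."""
    m = np.asarray(map_2d, dtype=float)
    roi.check_bounds(m.shape)
    patch = m[roi.slices()]
    valid = np.isfinite(patch)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)[roi.slices()]
    vals = patch[valid]
    if vals.size == 0:
        raise ValueError("ROI contains no valid pixels")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {"mean": float(np.mean(vals)), "sd": sd, "n": int(vals.size)}


def unpaired_t_test(sample_a, sample_b, welch: bool = False):
    """Two-sided unpaired t-test between two samples of ROI means.

    Pooled-variance (Student) form by default; ``welch=True`` drops the
    equal-variance assumption.  Two zero-variance samples with equal means
    give p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        df = a.size + b.size - 2
        return {"t": 0.0, "df": float(df), "p": 1.0, "significant": False}
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue),
            "significant": bool(res.pvalue < 0.05)}
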