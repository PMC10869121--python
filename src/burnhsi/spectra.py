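"""Wavelength grids, chromophore extinction library, reflectance/absorbance cubes.

The acquisition geometry this package targets is a visible/NIR hyperspectral
camera recording 400-1000 nm at 10 nm intervals (61 bands) over a 640x480 pixel
frame covering 32.6 x 24.5 mm, i.e. a ~51 um pixel pitch.  Diffuse reflectance
is obtained by ratioing the raw cube against a 99%-reflectance white standard,
and absorbance A(lambda) = -log10 R is the response variable of the chromophore
unmixing regression downstream.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "ChromophoreLibrary",
    "RawCube",
    "ReflectanceCube",
    "AbsorbanceCube",
    "ROI",
    "default_grid",
    "unmixing_grid",
    "load_extinction_library",
    "compute_reflectance",
    "absorbance_from_reflectance",
    "pixel_pitch_um",
    "DEFAULT_FOV_MM",
    "DEFAULT_FRAME_SHAPE",
]

#: Field of view (width, height) in mm and frame shape (rows, cols) of the
#: nominal acquisition system.
DEFAULT_FOV_MM = (32.6, 24.5)
DEFAULT_FRAME_SHAPE = (480, 640)

CHROMOPHORES = ("hbo", "hbr", "methb", "mel")
_TABLE_COLUMNS = ("eps_hbo", "eps_hbr", "eps_methb", "mu_mel")


def pixel_pitch_um(fov_mm: float = DEFAULT_FOV_MM[0], n_pixels: int = DEFAULT_FRAME_SHAPE[1]) -> float:
    """Lateral pixel pitch in micrometres from a field-of-view extent and pixel count."""
    if fov_mm <= 0 or n_pixels <= 0:
        raise ValueError("field of view and pixel count must be positive")
    return 1000.0 * fov_mm / n_pixels


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength grid in nm, restricted to 350-1100 nm."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(v) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if v[0] < 350.0 or v[-1] > 1100.0:
            raise ValueError("wavelengths must lie within [350, 1100] nm")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean selector for bands with lo <= lambda <= hi (inclusive)."""
        return (self.values >= lo) & (self.values <= hi)

    def subgrid(self, lo: float, hi: float) -> "WavelengthGrid":
        return WavelengthGrid(self.values[self.window(lo, hi)])


def default_grid() -> WavelengthGrid:
    """The 61-band acquisition grid: 400..1000 nm, 10 nm step."""
    return WavelengthGrid(np.arange(400.0, 1001.0, 10.0))


def unmixing_grid() -> WavelengthGrid:
    """The 14-band regression window: 550..680 nm, 10 nm step."""
    return WavelengthGrid(np.arange(550.0, 681.0, 10.0))


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Extinction spectra of the four skin chromophores on a common grid.

    ``eps_hbo``/``eps_hbr``/``eps_methb`` are tetramer molar extinction
    coefficients (L mol^-1 cm^-1); ``mu_mel`` is the melanin absorption
    spectrum (cm^-1 for the pure pigment), used directly as the fourth
    regression predictor.
    """

    grid: WavelengthGrid
    eps_hbo: np.ndarray
    eps_hbr: np.ndarray
    eps_methb: np.ndarray
    mu_mel: np.ndarray
    source: str = "unspecified"
    version: str = "0"

    def __post_init__(self):
        n = len(self.grid)
        for name in _TABLE_COLUMNS:
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (n,):
                raise ValueError(f"{name} must have one value per grid wavelength")
            object.__setattr__(self, name, a)
        self._sanity_check()

    def _sanity_check(self):
        wl = self.grid.values
        vis = (wl >= 450.0) & (wl <= 700.0)
        for name in _TABLE_COLUMNS:
            if np.any(getattr(self, name)[vis] <= 0):
                raise ValueError(f"{name} must be positive over 450-700 nm")
        # metHb is spectroscopically distinguished by its 600-650 nm band,
        # where oxy-Hb is nearly transparent; refuse a table without it.
        feat = (wl >= 600.0) & (wl <= 650.0)
        if feat.any() and not np.all(self.eps_methb[feat] > self.eps_hbo[feat]):
            raise ValueError("loaded table lacks the metHb 600-650 nm absorption feature")

    def design_matrix(self, intercept: bool = True) -> np.ndarray:
        """Regression predictors [eps_hbo, eps_hbr, eps_methb, mu_mel(, 1)] as columns."""
        cols = [self.eps_hbo, self.eps_hbr, self.eps_methb, self.mu_mel]
        if intercept:
            cols.append(np.ones(len(self.grid)))
        return np.column_stack(cols)

    def resample(self, grid: "WavelengthGrid") -> "ChromophoreLibrary":
        """Linear-interpolate the spectra onto another grid within support."""
        if grid.values[0] < self.grid.values[0] or grid.values[-1] > self.grid.values[-1]:
            raise ValueError("requested grid outside library support")
        cols = {name: np.interp(grid.values, self.grid.values, getattr(self, name))
                for name in _TABLE_COLUMNS}
        return ChromophoreLibrary(grid, cols["eps_hbo"], cols["eps_hbr"],
                                  cols["eps_methb"], cols["mu_mel"],
                                  source=self.source, version=self.version)

    def subset(self, lo: float, hi: float) -> "ChromophoreLibrary":
        sel = self.grid.window(lo, hi)
        return ChromophoreLibrary(
            WavelengthGrid(self.grid.values[sel]),
            self.eps_hbo[sel], self.eps_hbr[sel], self.eps_methb[sel], self.mu_mel[sel],
            source=self.source, version=self.version,
        )


def load_extinction_library(source=None, grid: WavelengthGrid | None = None) -> ChromophoreLibrary:
    """Load a chromophore extinction table and resample it onto ``grid``.

    Parameters
    ----------
    source
        Path, file object, or None for the packaged default table.  The table
        is delimited text with a header row containing ``wavelength_nm`` plus
        the four chromophore columns; ``#`` lines are comments.
    grid
        Target wavelength grid; defaults to the 550-680 nm unmixing window.
        Linear interpolation; requesting outside the table support is an error.
    """
    if grid is None:
        grid = unmixing_grid()
    if source is None:
        text = resources.files("burnhsi.data").joinpath("extinction_default.csv").read_text()
        table = pd.read_csv(_io.StringIO(text), comment="#")
        src_name = "packaged extinction_default.csv"
    else:
        table = pd.read_csv(source, comment="#", sep=None, engine="python")
        src_name = str(source)
    table.columns = [c.strip() for c in table.columns]
    if "wavelength_nm" not in table.columns:
        raise KeyError("extinction table must have a 'wavelength_nm' column")
    missing = [c for c in _TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"extinction table missing chromophore column(s): {missing}")
    wl = table["wavelength_nm"].to_numpy(dtype=float)
    order = np.argsort(wl)
    wl = wl[order]
    if grid.values[0] < wl[0] or grid.values[-1] > wl[-1]:
        raise ValueError(
            f"requested grid [{grid.values[0]}, {grid.values[-1]}] nm outside "
            f"table support [{wl[0]}, {wl[-1]}] nm"
        )
    cols = {c: np.interp(grid.values, wl, table[c].to_numpy(dtype=float)[order]) for c in _TABLE_COLUMNS}
    return ChromophoreLibrary(grid, cols["eps_hbo"], cols["eps_hbr"], cols["eps_methb"],
                              cols["mu_mel"], source=src_name, version="1")


@dataclass
class _Cube:
    data: np.ndarray           # rows x cols x bands
    grid: WavelengthGrid
    mask: np.ndarray = None    # True = valid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != len(self.grid):
            raise ValueError("band count must equal wavelength grid length")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:2]:
                raise ValueError("mask shape must match the image plane")

    @property
    def shape(self):
        return self.data.shape


class RawCube(_Cube):
    """Raw camera counts (or any unnormalized cube); no range validation."""


class ReflectanceCube(_Cube):
    """Diffuse reflectance raster; valid pixels lie in (0, 1.5]."""

    def __post_init__(self):
        super().__post_init__()
        bad = ~np.all(np.isfinite(self.data), axis=2)
        # negative reflectance is non-physical; >1.5 indicates a broken white reference
        with np.errstate(invalid="ignore"):
            bad |= np.any(self.data < 0, axis=2) | np.any(self.data > 1.5, axis=2)
        self.mask &= ~bad


class AbsorbanceCube(_Cube):
    """Base-10 absorbance raster A = -log10(R); masked pixels carry NaN."""


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest in pixel coordinates."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI must have positive extent")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI offsets must be non-negative")

    @classmethod
    def centered(cls, image_shape, size: int = 330) -> "ROI":
        """The default analysis window: ``size`` x ``size`` centered in the frame."""
        r0 = (image_shape[0] - size) // 2
        c0 = (image_shape[1] - size) // 2
        if r0 < 0 or c0 < 0:
            raise ValueError(f"{size}x{size} ROI does not fit in image {image_shape}")
        return cls(r0, c0, size, size)

    def check_bounds(self, image_shape):
        if self.row + self.height > image_shape[0] or self.col + self.width > image_shape[1]:
            raise ValueError(f"ROI {self} exceeds image bounds {image_shape}")

    def slices(self):
        return (slice(self.row, self.row + self.height), slice(self.col, self.col + self.width))


def compute_reflectance(raw, white, white_reflectance: float = 0.99,
                        dark=None) -> ReflectanceCube:
    """White-reference correction: R = white_reflectance * (raw - dark) / (white - dark).

    ``raw`` and ``white`` are cubes of raw camera counts sharing shape and
    grid.  Pixels where the white reference is <= 0 at any band cannot be
    normalised and are masked.  Dark-frame subtraction is optional and off by
    default.
    """
    if raw.data.shape != white.data.shape:
        raise ValueError("raw and white cubes must share shape")
    if not np.array_equal(raw.grid.values, white.grid.values):
        raise ValueError("raw and white cubes must share the wavelength grid")
    if not (0.0 < white_reflectance <= 1.0):
        raise ValueError("white_reflectance must be in (0, 1]")
    num = raw.data if dark is None else raw.data - dark.data
    den = white.data if dark is None else white.data - dark.data
    good_white = np.all(den > 0, axis=2)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    out *= white_reflectance
    mask = raw.mask & white.mask & good_white
    return ReflectanceCube(out, raw.grid, mask)


def absorbance_from_reflectance(cube: ReflectanceCube, floor: float = 1e-6) -> AbsorbanceCube:
    """A = -log10(max(R, floor)) on valid pixels; masked pixels become NaN."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    a = -np.log10(np.maximum(cube.data, floor))
    a[~cube.mask] = np.nan
    return AbsorbanceCube(a, cube.grid, cube.mask.copy())
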