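"""Ground-truthed synthetic data: sample tables, concentration fields, cubes.

No public dataset accompanies the burn-imaging protocol this package targets,
so every pipeline stage is exercised against synthetic inputs with pixel-exact
ground truth.  A ``Scenario`` states class- and time-conditional targets for
the hemoglobin indices (CHbT, StO2, StMet) of the three burn-severity classes
across the four acquisition times, together with between-subject spread,
within-wound spatial heterogeneity, and sensor noise.  The default scenario is
a *qualitative* emulation of the reported severity-dependent trajectories
(e.g. persistent methemoglobin rise in the deeper burns, transient rise in the
superficial one, hyperaemic CHbT increase only in the superficial burn); the
source protocol prints no numeric field values, so these defaults are the
package's own and are not measurement-derived.  Melanin is ~0 by default
(albino animals).

Generators are pure functions of (scenario, seed): sample tables of ROI-mean
features for the discriminant analysis, spatially correlated concentration
fields, and noisy hyperspectral reflectance cubes rendered through either the
Monte-Carlo-calibrated forward interpolator (``mc_interp``) or a modified
Beer-Lambert surrogate with fixed effective path length (``surrogate``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .spectra import (RawCube, ReflectanceCube, WavelengthGrid, ChromophoreLibrary,
                      load_extinction_library, unmixing_grid)
from .forward_model import (HB_MOLARITY_WHOLE_BLOOD, _LN10, default_skin_model)
from .cda import SampleTable, TIME_POINTS_S

__all__ = ["Scenario", "GroundTruthBundle", "default_scenario",
           "generate_sample_table", "generate_concentration_fields",
           "generate_hyperspectral_cube"]


@dataclass
class Scenario:
    """Study conditions for the synthetic generators.

    ``class_means`` maps class code -> feature name ("chbt", "sto2", "stmet")
    -> list of per-time-point means; ``subject_sd`` gives the between-subject
    SD per feature; ``field_sd`` the within-wound spatial SD per feature;
    ``correlation_length_px`` the Gaussian correlation length of the spatial
    heterogeneity; ``sensor_noise_sd`` the i.i.d. reflectance noise.
    """

    class_means: dict
    subject_sd: dict
    field_sd: dict
    correlation_length_px: float = 8.0
    sensor_noise_sd: float = 0.005
    image_shape: tuple = (128, 128)
    time_points_s: tuple = TIME_POINTS_S
    subjects_per_class: int = 7
    test_subjects_per_class: int = 4
    cm_mean: float = 0.0          # albino default: essentially no melanin
    version: str = "0"

    def __post_init__(self):
        for cls, feats in self.class_means.items():
            for name, vals in feats.items():
                vals = list(map(float, vals))
                if len(vals) != len(self.time_points_s):
                    raise ValueError(f"class {cls} feature {name}: need one mean per time point")
                lo, hi = 0.0, 100.0
                if any(v < lo or v > hi for v in vals):
                    raise ValueError(f"class {cls} feature {name}: means must be within [0, 100]")
                feats[name] = vals
        for d in (self.subject_sd, self.field_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("SDs must be non-negative")

    @property
    def class_codes(self):
        return sorted(self.class_means)

    @classmethod
    def from_yaml(cls, source) -> "Scenario":
        if hasattr(source, "read"):
            obj = yaml.safe_load(source)
        else:
            with open(source) as f:
                obj = yaml.safe_load(f)
        obj["class_means"] = {int(k): v for k, v in obj["class_means"].items()}
        if "image_shape" in obj:
            obj["image_shape"] = tuple(obj["image_shape"])
        if "time_points_s" in obj:
            obj["time_points_s"] = tuple(obj["time_points_s"])
        return cls(**obj)


def default_scenario() -> Scenario:
    """The packaged default scenario (see ``data/default_scenario.yaml``)."""
    text = resources.files("burnhsi.data").joinpath("default_scenario.yaml").read_text()
    import io as _io
    return Scenario.from_yaml(_io.StringIO(text))


def _clip_features(chbt, sto2, stmet):
    """Clip to physiologic bounds; saturations additionally satisfy
    StO2 + StMet <= 100 (the deoxy fraction cannot be negative)."""
    chbt = np.clip(chbt, 0.0, 100.0)
    sto2 = np.clip(sto2, 0.0, 100.0)
    stmet = np.clip(stmet, 0.0, 100.0)
    stmet = np.minimum(stmet, 100.0 - sto2)
    return chbt, sto2, stmet


def generate_sample_table(scenario: Scenario, seed: int = 0,
                          profile: str = "train"):
    """Draw a class/time-structured sample table of ROI-mean features.

    Per subject and time point, features are drawn from the class- and
    time-conditional normal distributions and clipped to physiologic bounds.
    The ``train`` profile uses ``subjects_per_class`` (7 x 3 x 4 = 84 rows by
    default); ``test`` uses ``test_subjects_per_class``.  Returns
    ``(SampleTable, truth frame)`` where truth holds the unclipped means.
    """
    if profile not in ("train", "test"):
        raise ValueError("profile must be 'train' or 'test'")
    n_subj = scenario.subjects_per_class if profile == "train" else scenario.test_subjects_per_class
    rng = np.random.default_rng(seed)
    rows = []
    truth = []
    for cls in scenario.class_codes:
        means = scenario.class_means[cls]
        for s in range(n_subj):
            subject = f"{profile}{cls}_{s + 1}"
            for it, t_s in enumerate(scenario.time_points_s):
                mu = {k: means[k][it] for k in ("chbt", "sto2", "stmet")}
                draw = {k: rng.normal(mu[k], scenario.subject_sd[k])
                        for k in ("chbt", "sto2", "stmet")}
                chbt, sto2, stmet = _clip_features(draw["chbt"], draw["sto2"], draw["stmet"])
                rows.append(dict(subject=subject, **{"class": cls}, t_s=t_s,
                                 chbt=float(chbt), sto2=float(sto2), stmet=float(stmet)))
                truth.append(dict(subject=subject, **{"class": cls}, t_s=t_s, **mu))
    return SampleTable(pd.DataFrame(rows)), pd.DataFrame(truth)


@dataclass
class GroundTruthBundle:
    """Pixel-exact truth for one synthetic wound image.

    ``fields`` holds rasters for cm, chbo, chbr, cmethb plus the derived
    indices chbt, sto2, stmet; the species rasters are primary and the index
    rasters satisfy the hemoglobin-index identities exactly (chbt is stored as
    the literal pixel-wise sum of the species).
    """

    fields: dict
    class_code: int
    time_s: float
    seed: int
    scenario_version: str = "0"

    @property
    def shape(self):
        return self.fields["chbt"].shape

    def concentration_stack(self) -> np.ndarray:
        """(rows, cols, 4) array ordered (cm, chbo, chbr, cmethb)."""
        return np.stack([self.fields[k] for k in ("cm", "chbo", "chbr", "cmethb")], axis=-1)


def _correlated_field(rng, shape, corr_len):
    """Unit-pixel-variance Gaussian random field with ~Gaussian correlation.

    The smoothed white noise is rescaled by the exact discrete kernel norm
    (the root sum of squares of the filter's delta response on this grid), so
    the per-pixel variance is 1 regardless of image size — for images smaller
    than the correlation length the field degenerates gracefully to a single
    N(0, 1) offset instead of amplifying numerical noise.
    """
    white = rng.standard_normal(shape)
    if corr_len <= 0:
        return white
    smooth = gaussian_filter(white, sigma=corr_len, mode="wrap")
    delta = np.zeros(shape)
    delta[0, 0] = 1.0
    norm = np.sqrt((gaussian_filter(delta, sigma=corr_len, mode="wrap") ** 2).sum())
    return smooth / norm


def generate_concentration_fields(scenario: Scenario, class_code: int,
                                  time_index: int, seed: int = 0,
                                  shape=None) -> GroundTruthBundle:
    """Spatially heterogeneous truth fields for one class and time point.

    Index fields (CHbT, StO2, StMet) are smooth correlated random fields with
    the scenario's class/time mean, spatial SD and correlation length, clipped
    to physiologic bounds; species fields follow pixel-wise.  Melanin is the
    scenario's (spatially uniform) ``cm_mean``.
    """
    if class_code not in scenario.class_means:
        raise KeyError(f"unknown class code {class_code}")
    if not 0 <= time_index < len(scenario.time_points_s):
        raise IndexError("time index out of range")
    shape = tuple(shape or scenario.image_shape)
    rng = np.random.default_rng(seed)
    means = scenario.class_means[class_code]
    raw = {}
    for name in ("chbt", "sto2", "stmet"):
        f = _correlated_field(rng, shape, scenario.correlation_length_px)
        raw[name] = means[name][time_index] + scenario.field_sd[name] * f
    chbt, sto2, stmet = _clip_features(raw["chbt"], raw["sto2"], raw["stmet"])

    chbo = chbt * sto2 / 100.0
    cmethb = chbt * stmet / 100.0
    chbr = np.maximum(chbt - chbo - cmethb, 0.0)
    chbt_exact = chbo + chbr + cmethb           # exact additivity by construction
    with np.errstate(invalid="ignore", divide="ignore"):
        sto2_exact = np.where(chbt_exact > 0, 100.0 * chbo / chbt_exact, 0.0)
        stmet_exact = np.where(chbt_exact > 0, 100.0 * cmethb / chbt_exact, 0.0)
    fields = {
        "cm": np.full(shape, float(scenario.cm_mean)),
        "chbo": chbo, "chbr": chbr, "cmethb": cmethb,
        "chbt": chbt_exact, "sto2": sto2_exact, "stmet": stmet_exact,
    }
    return GroundTruthBundle(fields=fields, class_code=class_code,
                             time_s=scenario.time_points_s[time_index], seed=seed,
                             scenario_version=scenario.version)


#: Surrogate forward-model constants: effective dermal path length (cm) and
#: wavelength-flat baseline absorbance.  Chosen to place absorbances in a
#: realistic 0.1-1.5 range across physiologic scenario concentrations while
#: keeping the darkest bands comfortably above the sensor noise floor;
#: arbitrary by design (the surrogate exists to give an exactly linear,
#: exactly invertible forward map for testing).
SURROGATE_PATH_CM = 0.025
SURROGATE_BASELINE = 0.3


def surrogate_absorbance(concentrations, library: ChromophoreLibrary,
                         path_cm: float = SURROGATE_PATH_CM,
                         baseline: float = SURROGATE_BASELINE) -> np.ndarray:
    """Modified Beer-Lambert surrogate: A = mua(conc, lambda) * path + baseline.

    ``concentrations`` is (..., 4) ordered (cm, chbo, chbr, cmethb); the
    absorbance is exactly linear in the extinction spectra, so OLS unmixing
    recovers the concentration-path products exactly.
    """
    c = np.asarray(concentrations, dtype=float)
    hb = _LN10 * HB_MOLARITY_WHOLE_BLOOD * (
        c[..., 1:2] * library.eps_hbo + c[..., 2:3] * library.eps_hbr
        + c[..., 3:4] * library.eps_methb) / 100.0
    mel = c[..., 0:1] * library.mu_mel / 100.0
    return (hb + mel) * path_cm + baseline


def generate_hyperspectral_cube(bundle: GroundTruthBundle,
                                mode: str = "surrogate",
                                noise_sd: float | None = None,
                                seed: int = 0,
                                interpolator=None,
                                grid: WavelengthGrid | None = None,
                                library: ChromophoreLibrary | None = None,
                                white_level: float = 0.8,
                                white_reflectance: float = 0.99):
    """Render truth fields to a noisy raw cube plus a flat white-reference cube.

    ``mode='surrogate'`` uses the linear Beer-Lambert surrogate;
    ``mode='mc_interp'`` interpolates reflectance spectra from a Monte Carlo
    calibration dataset (pass its ``interpolator``; truths outside the
    calibration box raise).  Bands of ``grid`` outside the forward model's
    spectral support are filled by nearest-edge extension — they carry no
    unmixing information (the regression window lies inside the support) but
    keep cubes full-width.  Sensor noise is i.i.d. Gaussian on reflectance.
    White-referencing is emulated with a flat white cube at ``white_level``
    counts: raw = R * white / white_reflectance, so that the standard
    correction recovers R.
    """
    grid = grid or unmixing_grid()
    rows, cols = bundle.shape
    conc = bundle.concentration_stack().reshape(-1, 4)

    if mode == "surrogate":
        if library is None:
            library = load_extinction_library(
                grid=WavelengthGrid(grid.values[(grid.values >= 450) & (grid.values <= 700)]))
        support = library.grid.values
        a = surrogate_absorbance(conc, library)
        r_support = 10.0 ** (-a)
    elif mode == "mc_interp":
        if interpolator is None:
            raise ValueError("mc_interp mode needs a calibration interpolator")
        support = interpolator.grid.values
        r_support = interpolator(conc)   # raises outside the calibration box
    else:
        raise ValueError(f"unknown forward mode {mode!r}")

    # place the supported bands, edge-extend the rest
    idx = np.clip(np.searchsorted(support, grid.values), 0, len(support) - 1)
    left = np.maximum(idx - 1, 0)
    nearer_left = (np.abs(grid.values - support[left])
                   < np.abs(grid.values - support[idx]))
    idx = np.where(nearer_left, left, idx)
    r_full = r_support[:, idx].reshape(rows, cols, len(grid))

    rng = np.random.default_rng(seed)
    sd = noise_sd if noise_sd is not None else 0.005
    r_noisy = r_full + rng.normal(0.0, sd, r_full.shape) if sd > 0 else r_full

    raw = RawCube(r_noisy * white_level / white_reflectance, grid)
    white = RawCube(np.full_like(r_noisy, white_level), grid)
    return raw, white
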