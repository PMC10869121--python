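"""Pixel-wise burn-depth classification images and occupancy rates.

The fitted canonical discriminant equations are applied to every valid pixel
of the hemoglobin-index maps: the pixel's (T, CHbT, StO2, StMet) feature
vector — T is the image's acquisition time, an observation-level covariate —
is expanded with the model's stored quadratic/standardization transform,
projected to canonical scores (z1, z2), and assigned to the nearest class
centroid.  The result is a label image over the burn-severity classes, from
which per-class occupancy rates over an ROI summarize the wound composition.
No spatial post-processing is applied: heterogeneity in the label image is
signal, not noise to be filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .cda import CDAModel, classify
from .spectra import ROI
from .unmixing import ParameterMaps

__all__ = ["SENTINEL", "DEFAULT_PALETTE", "LabelImage", "OccupancyReport",
           "classify_pixel_map", "occupancy_rates", "render_label_image"]

#: Label code for masked / undefined pixels.
SENTINEL = 0

#: Default rendering palette: sentinel near-black; classes colored by severity
#: (70C yellow, 78C orange, 98C red-brown).
DEFAULT_PALETTE = {
    SENTINEL: (30, 30, 30),
    1: (250, 220, 60),
    2: (245, 130, 30),
    3: (160, 30, 30),
}


@dataclass
class LabelImage:
    """Per-pixel burn-class codes (model class codes, SENTINEL = invalid)."""

    codes: np.ndarray            # (rows, cols) small ints
    class_codes: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        allowed = set(self.class_codes) | {SENTINEL}
        present = set(np.unique(self.codes).tolist())
        if not present <= allowed:
            raise ValueError(f"label image contains codes {present - allowed} "
                             f"outside the model's class set")

    @property
    def shape(self):
        return self.codes.shape

    @property
    def valid(self) -> np.ndarray:
        return self.codes != SENTINEL


@dataclass
class OccupancyReport:
    """Per-class fraction of valid ROI pixels (fractions sum to 1)."""

    fractions: dict              # class code -> fraction of valid pixels
    n_valid: int
    roi: ROI

    def as_dict(self) -> dict:
        return {"fractions": {str(k): v for k, v in self.fractions.items()},
                "n_valid": self.n_valid,
                "roi": [self.roi.row, self.roi.col, self.roi.height, self.roi.width]}


def classify_pixel_map(maps: ParameterMaps, time_s: float, model: CDAModel,
                       cube_id: str = "") -> LabelImage:
    """Apply the canonical discriminant equations to every valid pixel.

    ``time_s`` is the scalar acquisition time of the image.  Pixels that are
    masked, non-finite, or flagged undefined (CHbT = 0, where the saturations
    are conventions rather than measurements) receive the sentinel label.
    """
    if time_s < 0:
        raise ValueError("time since injury must be non-negative")
    chbt = maps["chbt"]
    sto2 = maps["sto2"]
    stmet = maps["stmet"]
    ok = maps.mask & ~maps.undefined
    ok &= np.isfinite(chbt) & np.isfinite(sto2) & np.isfinite(stmet)

    codes = np.full(maps.shape, SENTINEL, dtype=np.uint8)
    if ok.any():
        feats = np.column_stack([
            np.full(int(ok.sum()), float(time_s)),
            chbt[ok], sto2[ok], stmet[ok],
        ])
        z = model.predictor.transform(feats)
        codes[ok] = classify(model, z).astype(np.uint8)
    return LabelImage(codes=codes, class_codes=model.class_codes,
                      provenance={"time_s": float(time_s), "cube_id": cube_id,
                                  "model_classes": model.class_codes,
                                  "n_model_samples": model.n_samples})


def occupancy_rates(label: LabelImage, roi: ROI) -> OccupancyReport:
    """Per-class fraction of valid pixels inside the ROI."""
    roi.check_bounds(label.shape)
    patch = label.codes[roi.slices()]
    valid = patch != SENTINEL
    n = int(valid.sum())
    if n == 0:
        raise ValueError("ROI contains no validly classified pixels")
    fractions = {int(c): float(np.count_nonzero(patch[valid] == c)) / n
                 for c in label.class_codes}
    return OccupancyReport(fractions=fractions, n_valid=n, roi=roi)


def render_label_image(label: LabelImage, path, palette: dict | None = None):
    """Write the label image as an 8-bit color PNG (deterministic bytes).

    ``palette`` maps every class code plus the sentinel to an (R, G, B)
    triple; unmapped codes raise.
    """
    palette = DEFAULT_PALETTE if palette is None else palette
    needed = set(label.class_codes) | {SENTINEL}
    missing = needed - set(palette)
    if missing:
        raise KeyError(f"palette missing colors for codes {sorted(missing)}")
    rgb = np.zeros(label.shape + (3,), dtype=np.uint8)
    for code, color in palette.items():
        rgb[label.codes == code] = color
    Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    return path
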