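"""Cube, table and model file I/O.

Hyperspectral cubes travel as ENVI band-sequential rasters (a flat binary
file beside a text ``.hdr`` with samples/lines/bands/data type/wavelengths)
or as multi-band TIFF with wavelength metadata; the reader auto-detects the
dialect from the file extension.  Parameter maps are written as one
multi-band float TIFF plus a JSON sidecar carrying the unmixing provenance.
"""

from __future__ import annotations

import json
import os
import re
from pathlib import Path

import numpy as np
import tifffile

from .spectra import RawCube, ReflectanceCube, WavelengthGrid
from .unmixing import MAP_NAMES, ParameterMaps

__all__ = ["write_cube", "read_cube", "write_parameter_maps", "read_parameter_maps"]

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _header_path(path: Path) -> Path:
    return path.with_suffix(".hdr")


def write_cube(cube, path, dialect: str | None = None):
    """Write a cube as ENVI (``.img``/``.hdr``) or multi-band TIFF.

    The dialect follows the extension unless given explicitly: ``.tif``/
    ``.tiff`` means TIFF, anything else ENVI band-sequential float32.
    Wavelengths are stored in the header (ENVI) or the ImageDescription tag
    (TIFF).
    """
    path = Path(path)
    if dialect is None:
        dialect = "tiff" if path.suffix.lower() in (".tif", ".tiff") else "envi"
    rows, cols, bands = cube.data.shape
    if dialect == "tiff":
        meta = {"wavelength_nm": cube.grid.values.tolist()}
        tifffile.imwrite(path, cube.data.astype(np.float32).transpose(2, 0, 1),
                         description=json.dumps(meta))
        return path
    data = cube.data.astype(np.float32)
    data.transpose(2, 0, 1).tofile(path)       # band-sequential
    wl = ", ".join(f"{v:g}" for v in cube.grid.values)
    header = (
        "ENVI\n"
        "description = {burnhsi cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[np.dtype(np.float32)]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    _header_path(path).write_text(header)
    return path


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields = {}
    # collapse brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_cube(path, kind: str = "raw"):
    """Read an ENVI or TIFF cube; ``kind`` selects the returned container
    (``raw`` counts or ``reflectance``)."""
    path = Path(path)
    cls = {"raw": RawCube, "reflectance": ReflectanceCube}[kind]
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
        try:
            wl = json.loads(desc)["wavelength_nm"]
        except (json.JSONDecodeError, KeyError, TypeError) as err:
            raise ValueError(f"{path}: TIFF lacks wavelength metadata") from err
        data = np.moveaxis(data, 0, -1)
        if data.shape[-1] != len(wl):
            raise ValueError(f"{path}: {data.shape[-1]} bands but {len(wl)} wavelengths")
        return cls(data.astype(float), WavelengthGrid(np.asarray(wl, dtype=float)))

    hdr = _header_path(path)
    if not hdr.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as err:
        raise ValueError(f"{hdr}: missing required header field {err}") from err
    if "wavelength" not in fields:
        raise ValueError(f"{hdr}: missing wavelength list")
    wl = np.array([float(v) for v in fields["wavelength"].strip("{} ").split(",") if v.strip()])
    if len(wl) != bands:
        raise ValueError(f"{hdr}: {bands} bands but {len(wl)} wavelengths")
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"{hdr}: unsupported data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"{hdr}: only band-sequential (bsq) supported, got {interleave}")
    offset = int(fields.get("header offset", "0"))

    expected = rows * cols * bands * dtype.itemsize + offset
    actual = os.path.getsize(path)
    if actual != expected:
        raise ValueError(f"{path}: expected {expected} bytes "
                         f"({rows}x{cols}x{bands} {dtype}), found {actual}")
    data = np.fromfile(path, dtype=dtype, offset=offset).reshape(bands, rows, cols)
    return cls(data.transpose(1, 2, 0).astype(float), WavelengthGrid(wl))


def write_parameter_maps(maps: ParameterMaps, path, sidecar: dict | None = None):
    """Write parameter maps as a multi-band float32 TIFF + JSON sidecar.

    Band order follows ``MAP_NAMES`` (cm, chbo, chbr, cmethb, chbt, sto2,
    stmet, r2); the sidecar records the band order, unmixing window and any
    caller-supplied provenance.
    """
    path = Path(path)
    stack = np.stack([maps[name] for name in MAP_NAMES]).astype(np.float32)
    tifffile.imwrite(path, stack)
    meta = {
        "bands": list(MAP_NAMES),
        "window_nm": list(maps.window),
        "provenance": maps.provenance,
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_parameter_maps(path) -> ParameterMaps:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if list(meta["bands"]) != list(MAP_NAMES):
        raise ValueError(f"{path}: unexpected band order {meta['bands']}")
    maps = {name: stack[i].astype(float) for i, name in enumerate(MAP_NAMES)}
    mask = np.all(np.isfinite(stack), axis=0)
    chbt = maps["chbt"]
    return ParameterMaps(maps=maps, mask=mask,
                         undefined=mask & (chbt == 0),
                         clamped=np.zeros_like(mask),
                         extrapolated=np.zeros_like(mask),
                         window=tuple(meta["window_nm"]),
                         provenance=meta.get("provenance", {}))
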