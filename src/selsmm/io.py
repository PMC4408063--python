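"""Raster and spectral-library IO, and DN-to-radiance calibration.

Rasters are multiband reflectance or radiance images stored as 32-bit float
GeoTIFF (primary) or ENVI BSQ with a text ``.hdr`` (secondary).  Nodata is
carried as NaN inside a GeoTIFF and as a declared ``data ignore value`` in an
ENVI file; in memory it is an explicit boolean mask.

Spectral libraries are CSV files ``name,class,b1,...,bm`` holding one
reflectance spectrum per endmember, each labelled with a V-I-S land-cover
class (vegetation / impervious / soil / water, plus "other" for unassigned
candidates).
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "VIS_CLASSES",
    "ImageCube",
    "CalibrationParams",
    "SpectralLibrary",
    "read_raster",
    "write_raster",
    "read_spectral_library",
    "write_spectral_library",
    "dn_to_radiance",
]

#: Valid V-I-S land-cover class labels for endmembers.
VIS_CLASSES = ("vegetation", "impervious", "soil", "water", "other")

# ENVI nodata sentinel (ENVI headers cannot declare NaN portably).
_ENVI_IGNORE = -9999.0

# GeoTIFF tags used to round-trip an affine geotransform without GDAL.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922


@dataclass
class ImageCube:
    """A rows x cols x bands image with a nodata mask.

    ``data`` holds reflectance (unitless, typically in [0, 1]) or radiance
    (W m^-2 sr^-1 um^-1); all downstream operations only require that cube
    and library share units.  ``mask`` is True where a pixel is nodata.
    ``geotransform`` is the GDAL-style 6-tuple
    (x0, dx_col, dx_row, y0, dy_col, dy_row) mapping pixel (row, col) edges
    to map coordinates; None means pixel coordinates.
    """

    data: np.ndarray
    mask: np.ndarray | None = None
    band_names: list[str] | None = None
    geotransform: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageCube data must be (rows, cols, bands)")
        if self.n_bands < 2:
            raise ValueError(f"need at least 2 bands, got {self.n_bands}")
        if self.mask is None:
            self.mask = np.zeros(self.data.shape[:2], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match the spatial shape of data")
        if self.band_names is None:
            self.band_names = [f"b{i + 1}" for i in range(self.n_bands)]
        if len(self.band_names) != self.n_bands:
            raise ValueError("band_names length must equal band count")
        if not np.all(np.isfinite(self.data[~self.mask])):
            raise ValueError("unmasked pixels must be finite")
        if self.geotransform is not None:
            self.geotransform = tuple(float(v) for v in self.geotransform)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def unmasked_spectra(self) -> np.ndarray:
        """Return the (n_valid, bands) matrix of unmasked pixel spectra."""
        return self.data[~self.mask]


@dataclass
class CalibrationParams:
    """Per-band linear DN-to-radiance calibration coefficients.

    ``tm_minmax`` mode uses the radiances at the DN extremes
    (L = (Lmax - Lmin)/255 * DN + Lmin); ``gain_offset`` mode uses an
    absolute gain 1/a and an offset (L = DN/a + L0).
    """

    mode: str
    lmax: np.ndarray | None = None
    lmin: np.ndarray | None = None
    gain: np.ndarray | None = None
    offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("tm_minmax", "gain_offset"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")
        if self.mode == "tm_minmax":
            if self.lmax is None or self.lmin is None:
                raise ValueError("tm_minmax mode needs lmax and lmin")
            self.lmax = np.asarray(self.lmax, dtype=float)
            self.lmin = np.asarray(self.lmin, dtype=float)
            if self.lmax.shape != self.lmin.shape:
                raise ValueError("lmax and lmin must have the same length")
            if not np.all(self.lmax > self.lmin):
                raise ValueError("lmax must exceed lmin in every band")
        else:
            if self.gain is None or self.offset is None:
                raise ValueError("gain_offset mode needs gain and offset")
            self.gain = np.asarray(self.gain, dtype=float)
            self.offset = np.asarray(self.offset, dtype=float)
            if self.gain.shape != self.offset.shape:
                raise ValueError("gain and offset must have the same length")
            if not np.all(self.gain > 0):
                raise ValueError("gain must be positive in every band")

    @property
    def n_bands(self) -> int:
        arr = self.lmax if self.mode == "tm_minmax" else self.gain
        return len(arr)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(mode=doc["mode"], lmax=doc.get("lmax"), lmin=doc.get("lmin"),
                   gain=doc.get("gain"), offset=doc.get("offset"))

    def to_yaml(self, path: str | Path) -> Path:
        doc: dict = {"mode": self.mode}
        if self.mode == "tm_minmax":
            doc["lmax"] = [float(v) for v in self.lmax]
            doc["lmin"] = [float(v) for v in self.lmin]
        else:
            doc["gain"] = [float(v) for v in self.gain]
            doc["offset"] = [float(v) for v in self.offset]
        path = Path(path)
        path.write_text(yaml.safe_dump(doc))
        return path


@dataclass
class SpectralLibrary:
    """Reference endmember spectra with V-I-S class labels.

    ``spectra`` is (n_endmembers, n_bands); rows align with ``names`` and
    ``vis_class``.
    """

    names: list[str]
    vis_class: list[str]
    spectra: np.ndarray
    band_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=np.float64))
        if len(self.names) == 0:
            raise ValueError("library must contain at least one endmember")
        if self.spectra.shape[0] != len(self.names):
            raise ValueError("spectra rows must match number of names")
        if len(self.vis_class) != len(self.names):
            raise ValueError("one V-I-S class per endmember required")
        for c in self.vis_class:
            if c not in VIS_CLASSES:
                raise ValueError(f"unknown V-I-S class {c!r}")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")
        if np.any(self.spectra < 0):
            raise ValueError("spectra must be non-negative")
        if self.band_names is None:
            self.band_names = [f"b{i + 1}" for i in range(self.n_bands)]
        if len(self.band_names) != self.n_bands:
            raise ValueError("band_names length must equal band count")

    @property
    def n_endmembers(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def endmember_matrix(self) -> np.ndarray:
        """The (bands, endmembers) matrix C used by the mixture models."""
        return self.spectra.T.copy()

    def class_indices(self, vis: str) -> np.ndarray:
        """Indices of endmembers belonging to one V-I-S class."""
        return np.array([i for i, c in enumerate(self.vis_class) if c == vis],
                        dtype=int)

    def subset(self, indices: Sequence[int]) -> "SpectralLibrary":
        idx = list(indices)
        return SpectralLibrary(
            names=[self.names[i] for i in idx],
            vis_class=[self.vis_class[i] for i in idx],
            spectra=self.spectra[idx],
            band_names=list(self.band_names),
        )


# ---------------------------------------------------------------------------
# Raster IO


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("geotiff", "envi"):
            raise ValueError(f"unknown raster format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".img", ".bsq", ".dat", ""):
        return "envi"
    raise ValueError(f"cannot infer raster format from {path.name!r}")


def write_raster(cube: ImageCube, path: str | Path, format: str | None = None) -> Path:
    """Write a cube as 32-bit float GeoTIFF or ENVI BSQ; nodata preserved."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "geotiff":
        _write_geotiff(cube, path)
    else:
        _write_envi(cube, path)
    return path


def read_raster(path: str | Path, format: str | None = None,
                nodata: float | None = None) -> ImageCube:
    """Read a multiband raster; nodata (NaN, declared value, or ``nodata``)
    becomes the cube mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "geotiff":
        return _read_geotiff(path, nodata)
    return _read_envi(path, nodata)


def _write_geotiff(cube: ImageCube, path: Path) -> None:
    data = cube.data.astype(np.float32).copy()
    data[cube.mask] = np.nan
    # band-major (bands, rows, cols) pages
    arr = np.moveaxis(data, 2, 0)
    meta = {"band_names": list(cube.band_names)}
    extratags = []
    if cube.geotransform is not None:
        x0, dxc, dxr, y0, dyc, dyr = cube.geotransform
        if dxr != 0 or dyc != 0:
            raise ValueError("rotated geotransforms are not supported in GeoTIFF output")
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(dxc), abs(dyr), 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        ]
        meta["geotransform"] = list(cube.geotransform)
    tifffile.imwrite(path, arr, photometric="minisblack",
                     description=json.dumps(meta), extratags=extratags)


def _read_geotiff(path: Path, nodata: float | None) -> ImageCube:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim == 2:
        raise ValueError("single-band raster: at least 2 bands required")
    data = np.moveaxis(arr, 0, 2).astype(np.float64)
    band_names = None
    geotransform = None
    if desc:
        try:
            meta = json.loads(desc)
            band_names = meta.get("band_names")
            gt = meta.get("geotransform")
            geotransform = tuple(gt) if gt else None
        except (json.JSONDecodeError, AttributeError):
            pass
    mask = ~np.all(np.isfinite(data), axis=2)
    if nodata is not None:
        mask |= np.any(data == nodata, axis=2)
    data[mask] = 0.0
    return ImageCube(data=data, mask=mask, band_names=band_names,
                     geotransform=geotransform)


def _envi_hdr_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".hdr")


def _write_envi(cube: ImageCube, path: Path) -> None:
    data = cube.data.astype(np.float32).copy()
    data[cube.mask] = _ENVI_IGNORE
    rows, cols, bands = data.shape
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        f"data ignore value = {_ENVI_IGNORE}",
        "band names = {" + ", ".join(cube.band_names) + "}",
    ]
    if cube.geotransform is not None:
        x0, dxc, dxr, y0, dyc, dyr = cube.geotransform
        if dxr != 0 or dyc != 0:
            raise ValueError("rotated geotransforms are not supported in ENVI output")
        # signed pixel sizes (our dialect) so arbitrary geotransforms
        # survive the round trip
        lines.append(
            "map info = {Arbitrary, 1.0, 1.0, "
            f"{x0}, {y0}, {dxc}, {dyr}}}"
        )
    _envi_hdr_path(path).write_text("\n".join(lines) + "\n")
    # BSQ: band-sequential
    np.moveaxis(data, 2, 0).tofile(path)


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.lower()
            buf = val
        else:
            buf += " " + line
        if buf.count("{") > buf.count("}"):
            continue
        fields[key] = buf.strip()
        key = None
    return fields


def _read_envi(path: Path, nodata: float | None) -> ImageCube:
    hdr = _envi_hdr_path(path)
    if not hdr.exists():
        raise FileNotFoundError(f"file not found: {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    rows = int(fields["lines"])
    cols = int(fields["samples"])
    bands = int(fields["bands"])
    if bands < 2:
        raise ValueError("single-band raster: at least 2 bands required")
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only 32-bit float ENVI rasters are supported")
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    raw = np.fromfile(path, dtype="<f4" if int(fields.get("byte order", 0)) == 0
                      else ">f4")
    if raw.size != rows * cols * bands:
        raise ValueError("ENVI file size does not match header dimensions")
    data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2).astype(np.float64)
    band_names = None
    if "band names" in fields:
        band_names = [s.strip() for s in
                      fields["band names"].strip("{}").split(",")]
    geotransform = None
    if "map info" in fields:
        parts = [s.strip() for s in fields["map info"].strip("{}").split(",")]
        # Arbitrary, ref_col, ref_row, x0, y0, dx, dy
        x0, y0, dx, dy = (float(parts[i]) for i in (3, 4, 5, 6))
        geotransform = (x0, dx, 0.0, y0, 0.0, dy)
    mask = np.zeros((rows, cols), dtype=bool)
    ignore = fields.get("data ignore value")
    if ignore is not None:
        mask |= np.any(data == float(ignore), axis=2)
    mask |= ~np.all(np.isfinite(data), axis=2)
    if nodata is not None:
        mask |= np.any(data == nodata, axis=2)
    data[mask] = 0.0
    return ImageCube(data=data, mask=mask, band_names=band_names,
                     geotransform=geotransform)


# ---------------------------------------------------------------------------
# Spectral library CSV


def read_spectral_library(path: str | Path) -> SpectralLibrary:
    """Read a ``name,class,b1,...,bm`` CSV into a SpectralLibrary."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError("empty spectral library file") from exc
    if df.shape[0] == 0:
        raise ValueError("spectral library has no endmember rows")
    if list(df.columns[:2]) != ["name", "class"]:
        raise ValueError("library CSV must start with 'name,class' columns")
    band_cols = list(df.columns[2:])
    if len(band_cols) == 0:
        raise ValueError("library CSV has no band columns")
    for c in df["class"]:
        if c not in VIS_CLASSES:
            raise ValueError(f"unknown V-I-S class {c!r}")
    spectra = df[band_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(spectra)):
        raise ValueError("ragged spectra: missing or non-numeric band values")
    return SpectralLibrary(names=[str(n) for n in df["name"]],
                           vis_class=list(df["class"]),
                           spectra=spectra, band_names=[str(b) for b in band_cols])


def write_spectral_library(library: SpectralLibrary, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(library.spectra, columns=library.band_names)
    df.insert(0, "class", library.vis_class)
    df.insert(0, "name", library.names)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


# ---------------------------------------------------------------------------
# Radiometric calibration


def dn_to_radiance(cube: ImageCube, params: CalibrationParams) -> ImageCube:
    """Linear DN-to-radiance calibration, per band.

    tm_minmax:    L = (Lmax - Lmin) / 255 * DN + Lmin
    gain_offset:  L = DN / a + L0, with ``gain`` holding the multiplicative
                  absolute-calibration gain 1/a, so L = gain * DN + L0
    """
    if params.n_bands != cube.n_bands:
        raise ValueError(
            f"calibration has {params.n_bands} bands, cube has {cube.n_bands}")
    dn = cube.data
    if params.mode == "tm_minmax":
        scale = (params.lmax - params.lmin) / 255.0
        rad = scale[None, None, :] * dn + params.lmin[None, None, :]
    else:
        rad = params.gain[None, None, :] * dn + params.offset[None, None, :]
    rad = np.where(cube.mask[:, :, None], 0.0, rad)
    return ImageCube(data=rad, mask=cube.mask.copy(),
                     band_names=list(cube.band_names),
                     geotransform=cube.geotransform)
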