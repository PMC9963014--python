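"""Raster I/O and the shared grid data model.

All grids in the package are 2-D numpy arrays accompanied by a boolean
``valid_mask``; nodata is never encoded as a sentinel inside arithmetic.
GeoTIFF georeferencing (affine model tags, geo-key directory) and the GDAL
nodata tag are carried through opaquely so outputs stay aligned with their
inputs, but the package performs no reprojection or resampling of its own:
multi-date inputs are assumed co-registered.

Channel values default to the native 8-bit domain (0-255) carried as floats;
vegetation-index endpoint tables published for 8-bit imagery are only
meaningful on that scale.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import tifffile
from PIL import Image

from .errors import ContractError, RasterIOError

__all__ = [
    "RGBImage",
    "LabelMap",
    "read_rgb",
    "read_raster",
    "read_labels",
    "write_raster",
]

# TIFF tags carried through verbatim: GeoTIFF model/geokey tags.
_GEO_TAG_CODES = (33550, 33922, 34264, 34735, 34736, 34737)
_GDAL_NODATA = 42113

_TIFF_SUFFIXES = (".tif", ".tiff")


def _as_grid(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2:
        raise ContractError(f"{name} must be a 2-D array, got shape {a.shape}")
    return a


@dataclass
class RGBImage:
    """A 3-band image: per-pixel red/green/blue values plus a validity mask.

    Channels are stored as float64 regardless of the on-disk type.  The
    optional ``georeference`` is an opaque tuple of raw TIFF tag entries
    ``(code, dtype, count, value)`` copied from the source file and written
    back verbatim on output.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    valid_mask: np.ndarray | None = None
    georeference: tuple | None = None

    def __post_init__(self) -> None:
        self.red = _as_grid(self.red, "red").astype(np.float64)
        self.green = _as_grid(self.green, "green").astype(np.float64)
        self.blue = _as_grid(self.blue, "blue").astype(np.float64)
        if self.red.shape != self.green.shape or self.red.shape != self.blue.shape:
            raise ContractError("channel shapes differ")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.red.shape, dtype=bool)
        else:
            self.valid_mask = _as_grid(self.valid_mask, "valid_mask").astype(bool)
            if self.valid_mask.shape != self.red.shape:
                raise ContractError("valid_mask shape differs from channels")
        for name, ch in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            if not np.all(np.isfinite(ch[self.valid_mask])):
                raise ContractError(f"non-finite {name} values on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]


@dataclass
class LabelMap:
    """Per-pixel integer land-cover codes with a code->name mapping.

    ``class_names`` must cover every code present on valid pixels and should
    include a designated vegetation class (by default the code mapped to the
    name ``"vegetation"``).
    """

    labels: np.ndarray
    class_names: Mapping[int, str]
    valid_mask: np.ndarray | None = None
    georeference: tuple | None = None

    def __post_init__(self) -> None:
        self.labels = _as_grid(self.labels, "labels")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ContractError("labels must be integers")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.labels.shape, dtype=bool)
        else:
            self.valid_mask = _as_grid(self.valid_mask, "valid_mask").astype(bool)
            if self.valid_mask.shape != self.labels.shape:
                raise ContractError("valid_mask shape differs from labels")
        self.class_names = dict(self.class_names)
        present = np.unique(self.labels[self.valid_mask])
        unknown = [int(c) for c in present if int(c) not in self.class_names]
        if unknown:
            raise ContractError(f"codes {unknown} present but absent from class_names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def _read_tiff(path: str) -> tuple[np.ndarray, tuple | None, float | None]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = tif.series[0].asarray()
        geo: list[tuple] = []
        for code in _GEO_TAG_CODES:
            tag = page.tags.get(code)
            if tag is not None:
                geo.append((tag.code, int(tag.dtype), tag.count, tag.value))
        nodata = None
        ntag = page.tags.get(_GDAL_NODATA)
        if ntag is not None:
            try:
                nodata = float(str(ntag.value).strip())
            except ValueError:
                nodata = None
    return arr, tuple(geo) or None, nodata


def read_rgb(path: str | os.PathLike, channel_scale: str = "native8bit") -> RGBImage:
    """Read an RGB raster (GeoTIFF, PNG or JPEG) into an :class:`RGBImage`.

    The first three bands are taken as red, green, blue in that order.  An
    alpha band of 0, a declared nodata value, or non-finite samples mark a
    pixel invalid.  ``channel_scale="unit"`` divides channels by 255.
    """
    if channel_scale not in ("native8bit", "unit"):
        raise ContractError(f"unknown channel_scale {channel_scale!r}")
    path = os.fspath(path)
    if not os.path.exists(path):
        raise RasterIOError(f"no such file: {path}")
    geo: tuple | None = None
    nodata: float | None = None
    if path.lower().endswith(_TIFF_SUFFIXES):
        try:
            arr, geo, nodata = _read_tiff(path)
        except (tifffile.TiffFileError, OSError) as exc:
            raise RasterIOError(f"cannot read {path}: {exc}") from exc
    else:
        try:
            with Image.open(path) as im:
                if im.mode not in ("RGB", "RGBA"):
                    im = im.convert("RGBA" if "A" in im.mode else "RGB")
                arr = np.asarray(im)
        except (OSError, ValueError) as exc:
            raise RasterIOError(f"cannot read {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[0] in (3, 4) and arr.shape[2] not in (3, 4):
        arr = np.moveaxis(arr, 0, 2)  # band-first layout
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise RasterIOError(f"{path}: need at least 3 bands, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number):
        raise RasterIOError(f"{path}: non-numeric pixel type {arr.dtype}")
    arr = arr.astype(np.float64)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    mask = np.isfinite(r) & np.isfinite(g) & np.isfinite(b)
    if arr.shape[2] >= 4:
        mask &= arr[..., 3] != 0
    if nodata is not None:
        if np.isnan(nodata):
            pass  # already handled by the finite check
        else:
            mask &= ~((r == nodata) & (g == nodata) & (b == nodata))
    if channel_scale == "unit":
        r, g, b = r / 255.0, g / 255.0, b / 255.0
    r = np.where(mask, r, np.nan)
    g = np.where(mask, g, np.nan)
    b = np.where(mask, b, np.nan)
    return RGBImage(red=r, green=g, blue=b, valid_mask=mask, georeference=geo)


def _grid_payload(grid: Any) -> tuple[np.ndarray, np.ndarray, tuple | None, bool]:
    """Extract (values, mask, georeference, is_integer) from any grid object."""
    geo = getattr(grid, "georeference", None)
    mask = np.asarray(grid.valid_mask, dtype=bool)
    if hasattr(grid, "grades"):
        return np.asarray(grid.grades), mask, geo, True
    if hasattr(grid, "labels"):
        return np.asarray(grid.labels), mask, geo, True
    return np.asarray(grid.values), mask, geo, False


_INT_NODATA = -1


def write_raster(grid: Any, path: str | os.PathLike) -> str:
    """Write a single-band grid (index, FVC, grade, label or difference map).

    Real-valued grids are written float32 with NaN nodata; integer grids are
    written int32 with nodata -1.  The nodata value is declared via the GDAL
    nodata TIFF tag, and any georeference tags are passed through verbatim.
    """
    path = os.fspath(path)
    values, mask, geo, is_int = _grid_payload(grid)
    if values.shape != mask.shape:
        raise ContractError("grid values and mask shapes differ")
    if not is_int and not np.all(np.isfinite(np.asarray(values)[mask])):
        raise ContractError("non-finite values on valid pixels")
    if is_int:
        out = np.where(mask, values, _INT_NODATA).astype(np.int32)
        nodata_str = str(_INT_NODATA)
    else:
        out = np.where(mask, values, np.nan).astype(np.float32)
        nodata_str = "nan"
    extratags = [(_GDAL_NODATA, 2, None, nodata_str + "\x00", True)]
    for entry in geo or ():
        code, dtype, count, value = entry
        extratags.append((code, dtype, count, value, True))
    try:
        tifffile.imwrite(path, out, extratags=extratags)
    except OSError as exc:
        raise RasterIOError(f"cannot write {path}: {exc}") from exc
    return path


def read_raster(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, tuple | None]:
    """Read a single-band raster back as ``(values, valid_mask, georeference)``."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise RasterIOError(f"no such file: {path}")
    try:
        arr, geo, nodata = _read_tiff(path)
    except (tifffile.TiffFileError, OSError) as exc:
        raise RasterIOError(f"cannot read {path}: {exc}") from exc
    if arr.ndim != 2:
        raise RasterIOError(f"{path}: expected a single band, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        mask = np.isfinite(arr)
        if nodata is not None and not np.isnan(nodata):
            mask &= arr != nodata
    else:
        mask = np.ones(arr.shape, dtype=bool)
        if nodata is not None:
            mask = arr != int(nodata)
    return arr, mask, geo


def read_labels(path: str | os.PathLike, class_names: Mapping[int, str]) -> LabelMap:
    """Read a single-band integer raster as a :class:`LabelMap`.

    Raises if the raster contains codes absent from ``class_names``.
    """
    values, mask, geo = read_raster(path)
    if not np.issubdtype(values.dtype, np.integer):
        raise RasterIOError(f"{path}: label raster must be integer, got {values.dtype}")
    return LabelMap(labels=values, class_names=class_names, valid_mask=mask, georeference=geo)
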