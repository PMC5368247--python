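"""Altitude rasters (digital surface models) and their text/TIFF serialization.

A :class:`Raster` is a regular north-up grid of altitudes in metres.  Pixel
``(0, 0)`` sits at the north-west corner; ``origin`` holds the field
coordinates (metres, x east / y north) of that corner, so row indices grow
southward and column indices grow eastward.  Invalid pixels (photogrammetric
holes, out-of-field area) are tracked by a boolean validity mask.

Two on-disk forms are supported:

* ESRI ASCII grid (``.asc``) — plain text, used for small fixtures.
* Single-band float32 TIFF (``.tif``) via :mod:`tifffile`; resolution, origin
  and nodata are carried in the ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_raster", "write_raster", "RasterAlignmentError"]

_ASC_NODATA = -9999.0


class RasterAlignmentError(ValueError):
    """Raised when an operation requires two rasters on the same grid."""


@dataclass
class Raster:
    """A single-band altitude grid.

    Parameters
    ----------
    values
        2-D float array of altitudes in metres.
    resolution
        Ground size of one (square) pixel in metres; strictly positive.
    origin
        ``(x, y)`` field coordinates in metres of the north-west corner of
        pixel ``(0, 0)``.
    mask
        Boolean array, ``True`` where the pixel is valid.  Defaults to all
        valid; NaNs in ``values`` are always treated as invalid.
    """

    values: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not self.resolution > 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values shape")
        self.mask = self.mask & np.isfinite(self.values)
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_grid(self, other: "Raster", *, rtol: float = 1e-9) -> bool:
        """Whether *other* lives on the identical grid (shape, resolution, origin)."""
        return (
            self.shape == other.shape
            and np.isclose(self.resolution, other.resolution, rtol=rtol)
            and np.allclose(self.origin, other.origin, rtol=rtol, atol=1e-9)
        )

    def geometry_summary(self) -> str:
        return (
            f"shape={self.shape}, resolution={self.resolution} m/px, "
            f"origin=({self.origin[0]:.3f}, {self.origin[1]:.3f})"
        )

    def masked_values(self) -> np.ndarray:
        """Valid pixel values as a flat array."""
        return self.values[self.mask]


def write_raster(raster: Raster, path: str | Path) -> None:
    """Write *raster* as ``.asc`` (ESRI ASCII grid) or ``.tif``/``.tiff`` by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        _write_ascii(raster, path)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        _write_tiff(raster, path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


def read_raster(path: str | Path) -> Raster:
    """Read a raster written by :func:`write_raster`."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        return _read_ascii(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_tiff(path)
    raise ValueError(f"unsupported raster format: {path.suffix!r}")


def _write_ascii(raster: Raster, path: Path) -> None:
    nrows, ncols = raster.shape
    # ESRI convention: yllcorner is the southern edge.
    yll = raster.origin[1] - nrows * raster.resolution
    vals = np.where(raster.mask, raster.values, _ASC_NODATA)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {raster.resolution!r}\n"
        f"NODATA_value {_ASC_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6f")


def _read_ascii(path: Path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", _ASC_NODATA)
    mask = vals != nodata
    res = header["cellsize"]
    origin_y = header["yllcorner"] + header["nrows"] * res
    out = np.where(mask, vals, np.nan)
    return Raster(out, resolution=res, origin=(header["xllcorner"], origin_y), mask=mask)


def _write_tiff(raster: Raster, path: Path) -> None:
    import tifffile

    meta = {
        "resolution_m": raster.resolution,
        "origin_xy": list(raster.origin),
        "nodata": "nan",
    }
    vals = np.where(raster.mask, raster.values, np.nan).astype(np.float32)
    tifffile.imwrite(path, vals, description=json.dumps(meta))


def _read_tiff(path: Path) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        vals = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    res = float(meta.get("resolution_m", 1.0))
    origin = tuple(meta.get("origin_xy", (0.0, 0.0)))
    mask = np.isfinite(vals)
    return Raster(vals, resolution=res, origin=origin, mask=mask)
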