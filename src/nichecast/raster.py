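"""Georeferenced regular-grid rasters and stacks.

All maps in the pipeline live on a regular longitude/latitude grid
(WGS84 geographic coordinates).  Cell (0, 0) is the top-left cell; a
point maps to the cell whose half-open interval [edge, next-edge)
contains it.  Layers are stored and exchanged as ESRI ASCII grids
(plain-text ``.asc``), the simplest GDAL-standard single-band raster
format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WGS84 = "EPSG:4326"


class AlignmentError(ValueError):
    """Raised when rasters cannot be placed on a common grid."""


@dataclass(frozen=True)
class GridTransform:
    """Affine (axis-aligned) mapping between (col, row) and (lon, lat).

    ``west``/``north`` are the outer edges of the top-left cell; ``dx``
    and ``dy`` are positive cell sizes in degrees.  Row index grows
    southwards.
    """

    west: float
    north: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")

    def cell_center(self, row, col):
        """Longitude/latitude of the center of cell (row, col)."""
        lon = self.west + (np.asarray(col) + 0.5) * self.dx
        lat = self.north - (np.asarray(row) + 0.5) * self.dy
        return lon, lat

    def locate(self, lon, lat):
        """Cell (row, col) containing a point; half-open cell intervals."""
        col = np.floor((np.asarray(lon, dtype=float) - self.west) / self.dx)
        row = np.floor((self.north - np.asarray(lat, dtype=float)) / self.dy)
        return row.astype(int), col.astype(int)

    def extent(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer bounds for a given grid shape."""
        nrows, ncols = shape
        return (self.west, self.north - nrows * self.dy,
                self.west + ncols * self.dx, self.north)


@dataclass
class GridRaster:
    """One scalar layer on a regular lon/lat grid with a nodata mask."""

    values: np.ndarray
    nodata_mask: np.ndarray
    transform: GridTransform
    crs: str = WGS84

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValueError("non-finite values outside the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "GridRaster") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def valid_values(self) -> np.ndarray:
        """1-D array of values where the mask is clear."""
        return self.values[~self.nodata_mask]

    def cell_centers(self):
        """Arrays (lon, lat) of every cell center, row-major."""
        nrows, ncols = self.shape
        rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
        return self.transform.cell_center(rows, cols)

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "GridRaster":
        return GridRaster(values, self.nodata_mask if mask is None else mask,
                          self.transform, self.crs)

    def sample(self, lon, lat):
        """Values at points; NaN for off-grid or nodata cells."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        row, col = self.transform.locate(lon, lat)
        nrows, ncols = self.shape
        ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
        out = np.full(lon.shape, np.nan)
        rr, cc = row[ok], col[ok]
        vals = self.values[rr, cc]
        vals[self.nodata_mask[rr, cc]] = np.nan
        out[ok] = vals
        return out


def write_ascii_grid(raster: GridRaster, path: str | Path,
                     nodata_value: float = -9999.0) -> None:
    """Write a layer as an ESRI ASCII grid (square cells required)."""
    t = raster.transform
    if not np.isclose(t.dx, t.dy, rtol=1e-9):
        raise ValueError("ESRI ASCII grids require square cells")
    nrows, ncols = raster.shape
    vals = raster.values.copy()
    vals[raster.nodata_mask] = nodata_value
    header = (f"ncols {ncols}\nnrows {nrows}\n"
              f"xllcorner {float(t.west)!r}\nyllcorner {float(t.north - nrows * t.dy)!r}\n"
              f"cellsize {float(t.dx)!r}\nnodata_value {float(nodata_value)!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> GridRaster:
    """Read an ESRI ASCII grid into a :class:`GridRaster`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional nodata_value omitted
                break
        fh.seek(pos)
        body = np.loadtxt(fh, dtype=np.float64)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    body = body.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    mask = body == nodata
    cell = header["cellsize"]
    transform = GridTransform(west=header["xllcorner"],
                              north=header["yllcorner"] + nrows * cell,
                              dx=cell, dy=cell)
    vals = body.copy()
    vals[mask] = 0.0  # storage under mask is arbitrary but must stay finite
    return GridRaster(vals, mask, transform)


class RasterStack:
    """Ordered name -> GridRaster mapping on one shared grid.

    All layers share shape, transform, CRS and (by construction through
    :func:`align_stack`) the union nodata mask.
    """

    def __init__(self, layers: Mapping[str, GridRaster]):
        if not layers:
            raise ValueError("a stack needs at least one layer")
        self._layers = dict(layers)
        first = next(iter(self._layers.values()))
        for name, lyr in self._layers.items():
            if not lyr.same_grid(first):
                raise AlignmentError(f"layer {name!r} is not on the stack grid")

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self._layers.values())).shape

    @property
    def transform(self) -> GridTransform:
        return next(iter(self._layers.values())).transform

    @property
    def crs(self) -> str:
        return next(iter(self._layers.values())).crs

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __getitem__(self, name: str) -> GridRaster:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    @property
    def combined_mask(self) -> np.ndarray:
        """Union of the per-layer nodata masks."""
        mask = np.zeros(self.shape, dtype=bool)
        for lyr in self._layers.values():
            mask |= lyr.nodata_mask
        return mask

    def subset(self, names: Sequence[str]) -> "RasterStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return RasterStack({n: self._layers[n] for n in names})

    def drop(self, names: Iterable[str]) -> "RasterStack":
        drop = set(names)
        return RasterStack({n: l for n, l in self._layers.items() if n not in drop})

    def to_table(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Per-cell predictor table over valid cells.

        Indexed by flat cell index (row-major); one column per layer.
        An extra ``mask`` (True = exclude) is unioned with nodata.
        """
        bad = self.combined_mask
        if mask is not None:
            bad = bad | mask
        keep = ~bad.ravel()
        idx = np.flatnonzero(keep)
        data = {n: l.values.ravel()[idx] for n, l in self._layers.items()}
        return pd.DataFrame(data, index=idx)

    def items(self):
        return self._layers.items()


def align_stack(layers: Sequence[GridRaster] | Mapping[str, GridRaster]) -> RasterStack:
    """Place layers on the grid of the first layer and union nodata masks.

    Layers already on the reference grid pass through unchanged; others
    are resampled by nearest neighbour.  Disjoint extents raise
    :class:`AlignmentError`.
    """
    if isinstance(layers, Mapping):
        named = list(layers.items())
    else:
        named = [(f"layer{i + 1}", l) for i, l in enumerate(layers)]
    if not named:
        raise ValueError("need at least one layer")
    ref = named[0][1]
    out: dict[str, GridRaster] = {}
    for name, lyr in named:
        if lyr.same_grid(ref):
            out[name] = lyr
        else:
            out[name] = _resample_nearest(lyr, ref)
    union = np.zeros(ref.shape, dtype=bool)
    for lyr in out.values():
        union |= lyr.nodata_mask
    return RasterStack({n: GridRaster(l.values, union, ref.transform, ref.crs)
                        for n, l in out.items()})


def _resample_nearest(src: GridRaster, ref: GridRaster) -> GridRaster:
    w1, s1, e1, n1 = src.transform.extent(src.shape)
    w2, s2, e2, n2 = ref.transform.extent(ref.shape)
    if e1 <= w2 or e2 <= w1 or n1 <= s2 or n2 <= s1:
        raise AlignmentError("raster extents do not overlap")
    lon, lat = ref.cell_centers()
    row, col = src.transform.locate(lon, lat)
    nrows, ncols = src.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    vals = np.zeros(ref.shape)
    mask = np.ones(ref.shape, dtype=bool)
    rr = np.clip(row, 0, nrows - 1)
    cc = np.clip(col, 0, ncols - 1)
    vals[inside] = src.values[rr, cc][inside]
    mask[inside] = src.nodata_mask[rr, cc][inside]
    return GridRaster(vals, mask, ref.transform, ref.crs)


def extract_values(stack: RasterStack, occs) -> pd.DataFrame:
    """Predictor values at occurrence points.

    One row per occurrence that falls on a valid cell; occurrences on
    nodata cells or off the grid are dropped (count logged).  Cell
    lookup follows the half-open-interval convention, row 0 at top.
    """
    lon = np.asarray([r[1] for r in occs.records], dtype=float)
    lat = np.asarray([r[2] for r in occs.records], dtype=float)
    row, col = stack.transform.locate(lon, lat)
    nrows, ncols = stack.shape
    ok = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    bad_mask = stack.combined_mask
    rr = np.clip(row, 0, nrows - 1)
    cc = np.clip(col, 0, ncols - 1)
    ok &= ~bad_mask[rr, cc]
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("extract_values: dropped %d occurrence(s) on nodata or off-grid cells",
                       n_dropped)
    if not ok.any():
        raise ValueError("all occurrences fall off the grid or on nodata cells")
    flat = rr[ok] * ncols + cc[ok]
    data = {n: l.values[rr[ok], cc[ok]] for n, l in stack.items()}
    df = pd.DataFrame(data, index=flat)
    return df
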