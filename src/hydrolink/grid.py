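"""Georeferenced single-band rasters: container, file I/O, mosaicking, aggregation.

Conventions used throughout the package
---------------------------------------
* 0-based ``(row, col)`` indices, row 0 at the north edge.
* Cells are area cells: the center of cell ``(r, c)`` sits at
  ``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``
  where ``(origin_x, origin_y)`` is the outer corner of the top-left cell.
* ``cell_size`` is meters per cell edge; rasters must already be projected.
  Cell sizes below 0.01 look like degrees and trigger a warning.

Two on-disk formats are supported: single-band GeoTIFF (georeference in the
standard ModelPixelScale / ModelTiepoint / GDAL_NODATA tags, written and read
through :mod:`tifffile`) and the Esri ASCII grid
(NCOLS/NROWS/XLLCORNER/YLLCORNER/CELLSIZE/NODATA_VALUE header).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import (
    AlignmentError,
    EmptyInputError,
    GridFormatError,
    GridInvariantError,
    MosaicConflictError,
    ParameterError,
    UnsupportedInputError,
)

# GeoTIFF tag ids
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEGREE_CELLSIZE_THRESHOLD = 0.01  # cell sizes below this look geographic, not metric


@dataclass
class RasterGrid:
    """A rectangular, georeferenced, single-band raster with a nodata sentinel.

    Parameters
    ----------
    values
        2-D float array, row 0 northernmost. Nodata cells hold the sentinel.
    origin_x, origin_y
        Map coordinates (meters) of the outer corner of the top-left cell.
    cell_size
        Edge length of the square cells, meters.
    nodata
        Sentinel marking missing cells; must not collide with valid values.
    crs_tag
        Opaque CRS description carried through every operation unchanged.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = -9999.0
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise GridInvariantError(
                f"values must be 2-D, got {self.values.ndim}-D"
            )
        if self.cell_size <= 0:
            raise GridInvariantError(f"cell_size must be > 0, got {self.cell_size}")
        if 0 < self.cell_size < DEGREE_CELLSIZE_THRESHOLD:
            warnings.warn(
                f"cell_size {self.cell_size} is below {DEGREE_CELLSIZE_THRESHOLD}; "
                "this looks like a geographic (degree) raster — reproject to a "
                "metric CRS before hydrological analysis",
                stacklevel=3,
            )

    # -- basic geometry -----------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean grid, True where the cell holds a valid value."""
        return self.values != self.nodata

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of a cell center."""
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        """New grid sharing this grid's georeference but holding ``values``."""
        return replace(self, values=np.asarray(values, dtype=np.float64))

    def same_georeference(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=tol)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=tol)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
        )

    def validate(self) -> None:
        """Raise :class:`GridInvariantError` on any invariant violation."""
        if self.cell_size <= 0:
            raise GridInvariantError("cell_size must be > 0")
        if not np.all(np.isfinite(self.values[self.valid_mask()])):
            raise GridInvariantError("valid cells must be finite")


# -- file I/O ---------------------------------------------------------------


def read_grid(path: str | Path, format: str | None = None) -> RasterGrid:
    """Read a single-band raster from GeoTIFF or Esri ASCII grid.

    ``format`` is ``"geotiff"`` or ``"ascii_grid"``; when omitted it is
    inferred from the file suffix (.tif/.tiff vs .asc/.agr/.txt).
    """
    path = Path(path)
    if not path.exists():
        raise GridFormatError(f"{path}: file does not exist")
    fmt = format or _infer_format(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    raise UnsupportedInputError(f"unknown raster format {fmt!r}")


def write_grid(grid: RasterGrid, path: str | Path, format: str | None = None) -> Path:
    """Write a grid so that :func:`read_grid` reproduces it bit-exactly."""
    grid.validate()
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "geotiff":
        _write_geotiff(grid, path)
    elif fmt == "ascii_grid":
        _write_ascii(grid, path)
    else:
        raise UnsupportedInputError(f"unknown raster format {fmt!r}")
    return path


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    if suffix in {".asc", ".agr", ".txt"}:
        return "ascii_grid"
    raise UnsupportedInputError(
        f"{path}: cannot infer raster format from suffix {suffix!r}; "
        "pass format='geotiff' or 'ascii_grid'"
    )


def _read_geotiff(path: Path) -> RasterGrid:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            samples = page.tags.get("SamplesPerPixel")
            if (samples is not None and samples.value != 1) or (
                page.ndim > 2 and page.shape[-1] > 1 and len(page.shape) == 3
            ):
                raise UnsupportedInputError(
                    f"{path}: multiband GeoTIFF is not supported (single band required)"
                )
            values = page.asarray()
            scale = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
            tiepoint = page.tags.get(_TAG_MODEL_TIEPOINT)
            nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
            description = page.tags.get("ImageDescription")
            # materialize lazy tag values while the file is still open
            scale = None if scale is None else tuple(scale.value)
            tiepoint = None if tiepoint is None else tuple(tiepoint.value)
            nodata_tag = None if nodata_tag is None else str(nodata_tag.value)
            description = None if description is None else str(description.value)
    except UnsupportedInputError:
        raise
    except Exception as exc:  # tifffile raises assorted errors on garbled input
        raise GridFormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if values.ndim != 2:
        raise UnsupportedInputError(
            f"{path}: expected a single 2-D band, got shape {values.shape}"
        )
    if scale is None or tiepoint is None:
        raise GridFormatError(
            f"{path}: missing ModelPixelScale/ModelTiepoint georeference tags"
        )
    sx, sy = float(scale[0]), float(scale[1])
    if not math.isclose(sx, sy, rel_tol=1e-9):
        raise UnsupportedInputError(f"{path}: non-square cells {sx} x {sy}")
    tp = tiepoint
    # tiepoint maps raster (i, j) = (tp[0], tp[1]) to map (tp[3], tp[4])
    origin_x = float(tp[3]) - float(tp[0]) * sx
    origin_y = float(tp[4]) + float(tp[1]) * sy
    nodata = float(nodata_tag) if nodata_tag is not None else -9999.0
    crs_tag = description if description is not None else ""
    return RasterGrid(
        values=values.astype(np.float64),
        origin_x=origin_x,
        origin_y=origin_y,
        cell_size=sx,
        nodata=nodata,
        crs_tag=crs_tag,
    )


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    nodata_ascii = repr(float(grid.nodata)).encode() + b"\x00"
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (
            _TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0),
        ),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii),
    ]
    try:
        tifffile.imwrite(
            path,
            grid.values,
            description=grid.crs_tag,
            extratags=extratags,
        )
    except OSError as exc:
        raise GridFormatError(f"{path}: cannot write ({exc})") from exc


_ASCII_HEADER_KEYS = {
    "ncols",
    "nrows",
    "xllcorner",
    "yllcorner",
    "cellsize",
    "nodata_value",
}


def _read_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    data_start = 0
    try:
        with open(path) as fh:
            lines = fh.readlines()
    except OSError as exc:
        raise GridFormatError(f"{path}: cannot read ({exc})") from exc
    for lineno, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"{path}:{lineno + 1}: bad header value {parts[1]!r}"
                ) from exc
            data_start = lineno + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: ASCII grid header missing {key.upper()}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    try:
        values = np.loadtxt(lines[data_start:], dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise GridFormatError(
            f"{path}: bad data section starting line {data_start + 1} ({exc})"
        ) from exc
    if values.shape != (nrows, ncols):
        raise GridFormatError(
            f"{path}: header promises {nrows}x{ncols} but data is "
            f"{values.shape[0]}x{values.shape[1]}"
        )
    cell = header["cellsize"]
    return RasterGrid(
        values=values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cell,
        cell_size=cell,
        nodata=nodata,
    )


def _write_ascii(grid: RasterGrid, path: Path) -> None:
    yll = grid.origin_y - grid.nrows * grid.cell_size
    header = (
        f"NCOLS {grid.ncols}\n"
        f"NROWS {grid.nrows}\n"
        f"XLLCORNER {grid.origin_x!r}\n"
        f"YLLCORNER {yll!r}\n"
        f"CELLSIZE {grid.cell_size!r}\n"
        f"NODATA_VALUE {grid.nodata!r}\n"
    )
    try:
        with open(path, "w") as fh:
            fh.write(header)
            for row in grid.values:
                fh.write(" ".join(repr(float(v)) for v in row))
                fh.write("\n")
    except OSError as exc:
        raise GridFormatError(f"{path}: cannot write ({exc})") from exc


# -- mosaicking -------------------------------------------------------------


def mosaic(tiles: list[RasterGrid]) -> RasterGrid:
    """Merge grid-aligned tiles into one seamless grid.

    All tiles must share cell size, CRS tag and nodata, and their origins must
    differ by integer multiples of the cell size. Cells covered by no tile are
    nodata; cells covered by several tiles must agree wherever both are valid.
    """
    if not tiles:
        raise EmptyInputError("mosaic requires at least one tile")
    first = tiles[0]
    cell = first.cell_size
    for t in tiles[1:]:
        if not math.isclose(t.cell_size, cell, rel_tol=1e-12):
            raise AlignmentError(
                f"tile cell sizes differ: {cell} vs {t.cell_size}"
            )
        if t.crs_tag != first.crs_tag:
            raise AlignmentError("tiles carry different crs_tag values")
        if t.nodata != first.nodata:
            raise AlignmentError("tiles carry different nodata sentinels")
        for name, off in (
            ("x", (t.origin_x - first.origin_x) / cell),
            ("y", (t.origin_y - first.origin_y) / cell),
        ):
            if abs(off - round(off)) > 1e-6:
                raise AlignmentError(
                    f"tile origin_{name} offset {off} cells is not an integer "
                    "multiple of the cell size"
                )
    min_x = min(t.origin_x for t in tiles)
    max_y = max(t.origin_y for t in tiles)
    max_x = max(t.origin_x + t.ncols * cell for t in tiles)
    min_y = min(t.origin_y - t.nrows * cell for t in tiles)
    ncols = round((max_x - min_x) / cell)
    nrows = round((max_y - min_y) / cell)
    out = np.full((nrows, ncols), first.nodata, dtype=np.float64)
    for t in tiles:
        r0 = round((max_y - t.origin_y) / cell)
        c0 = round((t.origin_x - min_x) / cell)
        window = out[r0 : r0 + t.nrows, c0 : c0 + t.ncols]
        incoming = t.valid_mask()
        conflict = incoming & (window != first.nodata) & (window != t.values)
        if conflict.any():
            r, c = np.argwhere(conflict)[0]
            raise MosaicConflictError(
                f"tiles disagree at mosaic cell ({r0 + r}, {c0 + c}): "
                f"{window[r, c]} vs {t.values[r, c]}"
            )
        window[incoming] = t.values[incoming]
    return RasterGrid(
        values=out,
        origin_x=min_x,
        origin_y=max_y,
        cell_size=cell,
        nodata=first.nodata,
        crs_tag=first.crs_tag,
    )


# -- block aggregation ------------------------------------------------------


def aggregate(grid: RasterGrid, factor: int) -> RasterGrid:
    """Downsample by block-averaging ``factor`` x ``factor`` cells.

    Each output cell is the mean of the *valid* input cells in its block;
    blocks with no valid cell become nodata. Partial blocks at the south/east
    edges are averaged over the cells they do have, so no terrain is dropped.
    The origin is preserved and the cell size multiplied by ``factor``.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ParameterError(f"aggregation factor must be an integer >= 1, got {factor}")
    if factor == 1:
        return grid.copy_with(grid.values.copy())
    nrows_out = -(-grid.nrows // factor)
    ncols_out = -(-grid.ncols // factor)
    pad_r = nrows_out * factor - grid.nrows
    pad_c = ncols_out * factor - grid.ncols
    vals = np.pad(grid.values, ((0, pad_r), (0, pad_c)), constant_values=grid.nodata)
    valid = vals != grid.nodata
    vals = np.where(valid, vals, 0.0)
    blocks = vals.reshape(nrows_out, factor, ncols_out, factor)
    counts = valid.reshape(nrows_out, factor, ncols_out, factor).sum(axis=(1, 3))
    sums = blocks.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), grid.nodata)
    return RasterGrid(
        values=means,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        cell_size=grid.cell_size * factor,
        nodata=grid.nodata,
        crs_tag=grid.crs_tag,
    )
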