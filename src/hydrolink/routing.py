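"""D8 flow directions and flow accumulation.

Each land cell drains to the single 8-neighbor with the steepest
distance-weighted drop (distance 1 for cardinal, sqrt(2) for diagonal
neighbors, in cell units). Cells with no strictly lower land neighbor must
touch ocean or the grid border — they are outlets (code 0). Direction codes
use the power-of-two convention: 1=E, 2=SE, 4=S, 8=SW, 16=W, 32=NW, 64=N,
128=NE.

Accumulation counts, for every cell, the number of cells whose drainage
paths pass through it, *including the cell itself* (minimum 1). The count is
computed in topological order over the pointer forest, in linear time.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .condition import NEIGHBOR_OFFSETS
from .errors import CorruptedDirectionError, UnconditionedInputError
from .grid import RasterGrid
from .voids import NodataPartition, classify_nodata

#: D8 codes in the same order as NEIGHBOR_OFFSETS (E, SE, S, SW, W, NW, N, NE).
D8_CODES: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128)

#: code -> (drow, dcol)
CODE_TO_OFFSET: dict[int, tuple[int, int]] = dict(zip(D8_CODES, NEIGHBOR_OFFSETS))

OUTLET = 0
DIR_NODATA = -1

_SQRT2 = math.sqrt(2.0)
_DISTANCES = tuple(_SQRT2 if dr and dc else 1.0 for dr, dc in NEIGHBOR_OFFSETS)


@dataclass
class FlowDirectionGrid:
    """D8 pointer grid. ``codes[r, c]`` is a power-of-two code, 0 for an
    outlet, or -1 over ocean; georeference copied from the source DEM."""

    codes: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs_tag: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def land_mask(self) -> np.ndarray:
        return self.codes != DIR_NODATA

    def downstream(self, row: int, col: int) -> tuple[int, int] | None:
        """The cell this cell drains to, or None for outlets/ocean."""
        code = int(self.codes[row, col])
        if code in (OUTLET, DIR_NODATA):
            return None
        dr, dc = CODE_TO_OFFSET[code]
        return row + dr, col + dc


@dataclass
class FlowAccumulationGrid:
    """Upstream cell counts (self-inclusive); -1 over ocean."""

    counts: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    crs_tag: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def flow_direction(
    grid: RasterGrid, ocean: NodataPartition | None = None
) -> FlowDirectionGrid:
    """Assign a D8 code to every land cell of a conditioned DEM.

    Ties on the steepest drop are broken by the fixed precedence
    E, SE, S, SW, W, NW, N, NE (first maximal drop wins). Raises
    :class:`UnconditionedInputError` naming the first cell that neither
    descends nor touches an outlet.
    """
    if ocean is None:
        ocean = classify_nodata(grid)
    land = grid.valid_mask()
    nrows, ncols = grid.shape
    codes = np.full(grid.shape, DIR_NODATA, dtype=np.int16)
    vals = grid.values
    for r in range(nrows):
        for c in range(ncols):
            if not land[r, c]:
                continue
            best_drop = 0.0
            best_code = OUTLET
            at_outlet = r == 0 or c == 0 or r == nrows - 1 or c == ncols - 1
            for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
                nr, nc = r + dr, c + dc
                if not (0 <= nr < nrows and 0 <= nc < ncols):
                    at_outlet = True
                    continue
                if not land[nr, nc]:
                    at_outlet = True
                    continue
                drop = (vals[r, c] - vals[nr, nc]) / _DISTANCES[k]
                if drop > best_drop:
                    best_drop = drop
                    best_code = D8_CODES[k]
            if best_code == OUTLET and not at_outlet:
                raise UnconditionedInputError(
                    f"cell ({r}, {c}) has no lower neighbor and no ocean/border "
                    "adjacency; run depression filling first"
                )
            codes[r, c] = best_code
    return FlowDirectionGrid(
        codes=codes,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        cell_size=grid.cell_size,
        crs_tag=grid.crs_tag,
    )


def flow_accumulation(dirs: FlowDirectionGrid) -> FlowAccumulationGrid:
    """Count upstream cells (self-inclusive) by Kahn's algorithm over the
    pointer forest; raises :class:`CorruptedDirectionError` on a cycle."""
    codes = dirs.codes
    nrows, ncols = codes.shape
    land = dirs.land_mask()
    counts = np.where(land, 1, -1).astype(np.int64)
    indegree = np.zeros(codes.shape, dtype=np.int32)
    for r in range(nrows):
        for c in range(ncols):
            if land[r, c]:
                tgt = dirs.downstream(r, c)
                if tgt is not None:
                    tr, tc = tgt
                    if not (0 <= tr < nrows and 0 <= tc < ncols) or not land[tr, tc]:
                        raise CorruptedDirectionError(
                            f"cell ({r}, {c}) points at non-land cell ({tr}, {tc})"
                        )
                    indegree[tr, tc] += 1
    queue: deque[tuple[int, int]] = deque(
        (r, c)
        for r in range(nrows)
        for c in range(ncols)
        if land[r, c] and indegree[r, c] == 0
    )
    processed = 0
    while queue:
        r, c = queue.popleft()
        processed += 1
        tgt = dirs.downstream(r, c)
        if tgt is not None:
            tr, tc = tgt
            counts[tr, tc] += counts[r, c]
            indegree[tr, tc] -= 1
            if indegree[tr, tc] == 0:
                queue.append((tr, tc))
    n_land = int(land.sum())
    if processed != n_land:
        raise CorruptedDirectionError(
            f"direction grid contains a cycle ({n_land - processed} cells unresolved)"
        )
    return FlowAccumulationGrid(
        counts=counts,
        origin_x=dirs.origin_x,
        origin_y=dirs.origin_y,
        cell_size=dirs.cell_size,
        crs_tag=dirs.crs_tag,
    )


def direction_grid_to_raster(dirs: FlowDirectionGrid, nodata: float = -1.0) -> RasterGrid:
    """View the pointer grid as a RasterGrid for writing to disk."""
    return RasterGrid(
        values=dirs.codes.astype(np.float64),
        origin_x=dirs.origin_x,
        origin_y=dirs.origin_y,
        cell_size=dirs.cell_size,
        nodata=nodata,
        crs_tag=dirs.crs_tag,
    )


def accumulation_grid_to_raster(
    acc: FlowAccumulationGrid, nodata: float = -1.0
) -> RasterGrid:
    return RasterGrid(
        values=acc.counts.astype(np.float64),
        origin_x=acc.origin_x,
        origin_y=acc.origin_y,
        cell_size=acc.cell_size,
        nodata=nodata,
        crs_tag=acc.crs_tag,
    )


def raster_to_direction_grid(grid: RasterGrid) -> FlowDirectionGrid:
    """Inverse of :func:`direction_grid_to_raster` (for CLI round-trips)."""
    codes = np.where(grid.valid_mask(), grid.values, DIR_NODATA).astype(np.int16)
    valid_codes = set(D8_CODES) | {OUTLET, DIR_NODATA}
    bad = ~np.isin(codes, sorted(valid_codes))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise CorruptedDirectionError(
            f"cell ({r}, {c}) holds {codes[r, c]}, not a D8 code"
        )
    return FlowDirectionGrid(
        codes=codes,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        cell_size=grid.cell_size,
        crs_tag=grid.crs_tag,
    )


def raster_to_accumulation_grid(grid: RasterGrid) -> FlowAccumulationGrid:
    counts = np.where(grid.valid_mask(), grid.values, -1).astype(np.int64)
    return FlowAccumulationGrid(
        counts=counts,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        cell_size=grid.cell_size,
        crs_tag=grid.crs_tag,
    )
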