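"""Hydrologic enforcement: raise depressions so every land cell drains.

Implements priority-flood with an epsilon gradient. Cells are processed from
the drainage targets (ocean nodata and the grid border) inward in ascending
elevation order; each newly reached cell is raised, if necessary, to the
elevation of the cell it was reached from plus ``epsilon``. The result is the
minimal raising (up to the epsilon steps) such that every terrestrial cell
has a strictly descending 8-neighbor path to an outlet.

Determinism: the priority queue orders by (elevation, row, col), so the
output is bit-identical across runs regardless of traversal order.
"""

from __future__ import annotations

import heapq

import numpy as np

from .errors import EmptyInputError, ParameterError
from .grid import RasterGrid
from .voids import NodataPartition, classify_nodata

DEFAULT_EPSILON = 0.001  # meters; the minimal enforced downhill step

# D8 neighbor offsets, in the package-wide precedence order E, SE, S, SW, W, NW, N, NE
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
)


def fill_depressions(
    grid: RasterGrid,
    epsilon: float = DEFAULT_EPSILON,
    ocean: NodataPartition | None = None,
) -> RasterGrid:
    """Return a conditioned copy of ``grid`` in which every land cell drains.

    Voids must already be filled (interior nodata is treated as ocean here,
    which a filled grid no longer has). ``epsilon`` (> 0, meters) is the
    minimum elevation step imposed along previously undrained paths.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be > 0, got {epsilon}")
    if ocean is None:
        ocean = classify_nodata(grid)
    land = grid.valid_mask()
    if not land.any():
        raise EmptyInputError("grid is entirely nodata; nothing to condition")

    nrows, ncols = grid.shape
    out = grid.values.copy()
    visited = np.zeros(grid.shape, dtype=bool)
    water = ~land  # ocean nodata and (already filled ⇒ absent) voids

    # Seed: every land cell 8-adjacent to water or to the grid edge is already
    # at an outlet and keeps its elevation.
    heap: list[tuple[float, int, int]] = []
    for r in range(nrows):
        for c in range(ncols):
            if not land[r, c]:
                continue
            at_edge = r == 0 or c == 0 or r == nrows - 1 or c == ncols - 1
            if not at_edge:
                for dr, dc in NEIGHBOR_OFFSETS:
                    if water[r + dr, c + dc]:
                        at_edge = True
                        break
            if at_edge:
                visited[r, c] = True
                heap.append((out[r, c], r, c))
    heapq.heapify(heap)

    while heap:
        elev, r, c = heapq.heappop(heap)
        for dr, dc in NEIGHBOR_OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and land[nr, nc] and not visited[nr, nc]:
                visited[nr, nc] = True
                raised = max(out[nr, nc], elev + epsilon)
                out[nr, nc] = raised
                heapq.heappush(heap, (raised, nr, nc))

    return grid.copy_with(out)


def drains_everywhere(grid: RasterGrid, ocean: NodataPartition | None = None) -> bool:
    """Check the drainage guarantee: every land cell has a strictly lower
    8-neighbor or touches ocean/border (a local check that, together with the
    finiteness of strictly descending chains, implies a descending path to an
    outlet from every cell)."""
    if ocean is None:
        ocean = classify_nodata(grid)
    land = grid.valid_mask()
    nrows, ncols = grid.shape
    for r in range(nrows):
        for c in range(ncols):
            if not land[r, c]:
                continue
            ok = r == 0 or c == 0 or r == nrows - 1 or c == ncols - 1
            if not ok:
                for dr, dc in NEIGHBOR_OFFSETS:
                    nr, nc = r + dr, c + dc
                    if not land[nr, nc] or grid.values[nr, nc] < grid.values[r, c]:
                        ok = True
                        break
            if not ok:
                return False
    return True
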