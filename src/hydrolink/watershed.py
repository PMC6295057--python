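"""Watershed (upstream-area) delineation from a D8 pointer grid.

``delineate`` walks the flow graph *backwards* from the pour cell by
breadth-first search over upstream adjacency — linear in the size of the
watershed. ``oracle_delineate`` is the deliberately naive cross-check: for
every land cell, walk its forward path and keep the cell iff the path visits
the pour cell. The two must agree exactly; the oracle is size-guarded since
its cost grows with (cells x path length).

Masks are held in memory only. The national-scale use case delineates one
watershed per region and never persists them individually — only the final
upstream table is written.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from .condition import NEIGHBOR_OFFSETS
from .errors import InvalidPourError, ParameterError
from .routing import D8_CODES, DIR_NODATA, FlowDirectionGrid
from .regions import PourPoint

ORACLE_MAX_CELLS = 10_000


@dataclass
class WatershedMask:
    """The set of cells whose D8 paths reach a region's pour cell."""

    region_id: str
    cells: frozenset[tuple[int, int]]

    def __contains__(self, cell: tuple[int, int]) -> bool:
        return cell in self.cells

    def __len__(self) -> int:
        return len(self.cells)


# code that the neighbor at offset (dr, dc) must hold to drain *into* the
# current cell: the opposite of the offset's own code
_UPSTREAM_CODE: dict[tuple[int, int], int] = {
    (dr, dc): D8_CODES[NEIGHBOR_OFFSETS.index((-dr, -dc))]
    for dr, dc in NEIGHBOR_OFFSETS
}


def delineate(dirs: FlowDirectionGrid, pour: PourPoint) -> WatershedMask:
    """Reverse-flow BFS from the pour cell; exact and linear in mask size."""
    nrows, ncols = dirs.shape
    r0, c0 = pour.row, pour.col
    if not (0 <= r0 < nrows and 0 <= c0 < ncols) or dirs.codes[r0, c0] == DIR_NODATA:
        raise InvalidPourError(
            f"pour point for {pour.region_id!r} at ({r0}, {c0}) is not a land cell"
        )
    members = {(r0, c0)}
    queue: deque[tuple[int, int]] = deque([(r0, c0)])
    codes = dirs.codes
    while queue:
        r, c = queue.popleft()
        for (dr, dc), want in _UPSTREAM_CODE.items():
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and codes[nr, nc] == want:
                cell = (nr, nc)
                if cell not in members:
                    members.add(cell)
                    queue.append(cell)
    return WatershedMask(region_id=pour.region_id, cells=frozenset(members))


def oracle_delineate(dirs: FlowDirectionGrid, pour: PourPoint) -> WatershedMask:
    """Brute-force definition of the watershed: forward-walk every cell's path.

    Guarded to grids of at most ``ORACLE_MAX_CELLS`` cells; this is a test
    oracle, not a production path.
    """
    nrows, ncols = dirs.shape
    if nrows * ncols > ORACLE_MAX_CELLS:
        raise ParameterError(
            f"oracle_delineate is limited to {ORACLE_MAX_CELLS} cells "
            f"({nrows}x{ncols} given)"
        )
    r0, c0 = pour.row, pour.col
    if not (0 <= r0 < nrows and 0 <= c0 < ncols) or dirs.codes[r0, c0] == DIR_NODATA:
        raise InvalidPourError(
            f"pour point for {pour.region_id!r} at ({r0}, {c0}) is not a land cell"
        )
    members = set()
    for r in range(nrows):
        for c in range(ncols):
            if dirs.codes[r, c] == DIR_NODATA:
                continue
            cur = (r, c)
            for _ in range(nrows * ncols):
                if cur == (r0, c0):
                    members.add((r, c))
                    break
                nxt = dirs.downstream(*cur)
                if nxt is None:
                    break
                cur = nxt
    return WatershedMask(region_id=pour.region_id, cells=frozenset(members))
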