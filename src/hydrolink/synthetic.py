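"""Synthetic DEM + region fixtures with known upstream ground truth.

Four scene families cover the structures the pipeline assumes:

* ``linear_chain_scene`` — the maximal thought experiment: one straight
  river descending monotonically, villages strung along it one after
  another. Village k (0-based from the headwater) has exactly k upstream
  villages; the realized relation total is n(n-1)/2.
* ``cone_island_scene`` — the minimal thought experiment: a conical island
  with villages along the shoreline, every upstream list empty. The cone's
  contours are squares (Chebyshev metric) rather than circles: under D8 a
  Euclidean cone develops along-shore drift (a shore cell can have a
  slightly lower shore neighbor), which would leak flow between shoreline
  villages; with Chebyshev contours every shoreline cell is an outlet and
  descent is exactly radial, so the scenario's defining property — zero
  relations — holds by construction.
* ``confluence_scene`` — a Y-shaped valley: two headwater arms joining into
  a trunk; the trunk village lists both arms, the arms list nothing.
* ``random_terrain_scene`` — seeded midpoint-displacement terrain with an
  ocean margin and Voronoi villages; its expected table is computed by the
  brute-force watershed oracle, never by the production traversal, making it
  the end-to-end regression fixture.

All scenes are bit-reproducible from (seed, parameters). Elevations are in
meters on a 90 m grid — the analysis resolution the tool was designed
around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

from .condition import fill_depressions
from .errors import ParameterError
from .grid import RasterGrid
from .regions import RegionRecord, RegionSet, rasterize, place_pour_points
from .routing import flow_accumulation, flow_direction
from .table import UpstreamTable, extract_upstream
from .voids import classify_nodata, fill_voids
from .watershed import oracle_delineate

CELL = 90.0
NODATA = -9999.0


@dataclass
class SyntheticScene:
    """A generated fixture: terrain, regions, and the expected upstream table."""

    grid: RasterGrid
    regions: RegionSet
    expected: UpstreamTable
    seed: int
    descriptor: dict = field(default_factory=dict)


def _cells_to_polygon(cells, grid: RasterGrid):
    """Union of the cell footprints — contains exactly those cells' centers."""
    cs = grid.cell_size
    boxes = [
        box(
            grid.origin_x + c * cs,
            grid.origin_y - (r + 1) * cs,
            grid.origin_x + (c + 1) * cs,
            grid.origin_y - r * cs,
        )
        for r, c in cells
    ]
    return unary_union(boxes)


def _region_label(prefix: str, k: int, n: int) -> str:
    width = max(2, len(str(n)))
    return f"{prefix}{k + 1:0{width}d}"


def linear_chain_scene(
    n_villages: int, cells_per_village: int = 3, seed: int = 0
) -> SyntheticScene:
    """A single monotone river with ``n_villages`` consecutive villages.

    The river is one cell wide, flanked by ocean, descending west to east;
    village k covers ``cells_per_village`` consecutive river cells. Expected
    upstream lists have lengths 0, 1, ..., n-1 from headwater down.
    """
    if n_villages < 1 or cells_per_village < 1:
        raise ParameterError("n_villages and cells_per_village must be >= 1")
    ncols = n_villages * cells_per_village
    values = np.full((3, ncols), NODATA)
    values[1, :] = np.arange(ncols, 0, -1, dtype=np.float64)  # descends east
    grid = RasterGrid(
        values=values, origin_x=0.0, origin_y=3 * CELL, cell_size=CELL, nodata=NODATA
    )
    records = []
    ids = [_region_label("V", k, n_villages) for k in range(n_villages)]
    for k, rid in enumerate(ids):
        cells = [(1, c) for c in range(k * cells_per_village, (k + 1) * cells_per_village)]
        records.append(RegionRecord(rid, _cells_to_polygon(cells, grid)))
    expected = UpstreamTable(entries={rid: list(ids[:k]) for k, rid in enumerate(ids)})
    return SyntheticScene(
        grid=grid,
        regions=RegionSet(records),
        expected=expected,
        seed=seed,
        descriptor={
            "scene": "chain",
            "n_villages": n_villages,
            "cells_per_village": cells_per_village,
        },
    )


def cone_island_scene(
    radius_cells: int, n_villages: int, seed: int = 0
) -> SyntheticScene:
    """A conical island with ``n_villages`` contiguous shoreline villages.

    Elevation decreases outward with Chebyshev ring index, so every
    shoreline cell is an outlet and no village is upstream of any other:
    the expected table is all-empty.
    """
    if radius_cells < 1:
        raise ParameterError("radius_cells must be >= 1")
    shoreline = _ring_cells(radius_cells)
    if n_villages < 1 or n_villages > len(shoreline):
        raise ParameterError(
            f"n_villages must be in [1, {len(shoreline)}] for radius {radius_cells}"
        )
    size = 2 * radius_cells + 3  # 1-cell ocean margin all around
    center = radius_cells + 1
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    cheb = np.maximum(np.abs(rr - center), np.abs(cc - center))
    values = np.where(
        cheb <= radius_cells, (radius_cells + 1 - cheb) * 10.0, NODATA
    )
    grid = RasterGrid(
        values=values, origin_x=0.0, origin_y=size * CELL, cell_size=CELL, nodata=NODATA
    )
    # split the shoreline walk into n contiguous arcs of near-equal length
    ids = [_region_label("S", k, n_villages) for k in range(n_villages)]
    bounds = np.linspace(0, len(shoreline), n_villages + 1).astype(int)
    records = []
    for k, rid in enumerate(ids):
        arc = [(r + center, c + center) for r, c in shoreline[bounds[k] : bounds[k + 1]]]
        records.append(RegionRecord(rid, _cells_to_polygon(arc, grid)))
    expected = UpstreamTable(entries={rid: [] for rid in ids})
    return SyntheticScene(
        grid=grid,
        regions=RegionSet(records),
        expected=expected,
        seed=seed,
        descriptor={
            "scene": "cone",
            "radius_cells": radius_cells,
            "n_villages": n_villages,
        },
    )


def _ring_cells(radius: int) -> list[tuple[int, int]]:
    """Cells at Chebyshev distance ``radius`` from (0, 0), walked clockwise
    from the northwest corner."""
    r = radius
    top = [(-r, c) for c in range(-r, r + 1)]
    right = [(rr, r) for rr in range(-r + 1, r + 1)]
    bottom = [(r, c) for c in range(r - 1, -r - 1, -1)]
    left = [(rr, -r) for rr in range(r - 1, -r, -1)]
    return top + right + bottom + left


def confluence_scene(arm_length: int = 5, seed: int = 0) -> SyntheticScene:
    """A Y-shaped valley: two diagonal headwater arms joining a straight trunk.

    Three villages — west arm, east arm, trunk (which includes the junction
    cell). Expected: the trunk lists both arms; the arms list nothing.
    """
    if arm_length < 1:
        raise ParameterError("arm_length must be >= 1")
    L = arm_length
    trunk_len = arm_length + 1  # junction + L cells below it
    nrows = L + trunk_len + 2
    ncols = 2 * L + 3
    jr, jc = 1 + L, 1 + L
    values = np.full((nrows, ncols), NODATA)
    # trunk: junction at elevation trunk_len, descending south to 1
    for t in range(trunk_len):
        values[jr + t, jc] = float(trunk_len - t)
    # arms: rise diagonally NW and NE from the junction
    west, east = [], []
    for k in range(L):
        elev = float(trunk_len + k + 1)
        w = (jr - 1 - k, jc - 1 - k)
        e = (jr - 1 - k, jc + 1 + k)
        values[w] = elev
        values[e] = elev
        west.append(w)
        east.append(e)
    grid = RasterGrid(
        values=values, origin_x=0.0, origin_y=nrows * CELL, cell_size=CELL, nodata=NODATA
    )
    trunk_cells = [(jr + t, jc) for t in range(trunk_len)]
    records = [
        RegionRecord("ARM_E", _cells_to_polygon(east, grid)),
        RegionRecord("ARM_W", _cells_to_polygon(west, grid)),
        RegionRecord("TRUNK", _cells_to_polygon(trunk_cells, grid)),
    ]
    expected = UpstreamTable(
        entries={"ARM_E": [], "ARM_W": [], "TRUNK": ["ARM_E", "ARM_W"]}
    )
    return SyntheticScene(
        grid=grid,
        regions=RegionSet(records),
        expected=expected,
        seed=seed,
        descriptor={"scene": "confluence", "arm_length": arm_length},
    )


def _midpoint_displacement(size: int, rng: np.random.Generator, roughness: float) -> np.ndarray:
    """Diamond-square fractal surface on a (2^k + 1) square grid."""
    n = 1
    while n + 1 < size:
        n *= 2
    side = n + 1
    z = np.zeros((side, side))
    z[0, 0], z[0, -1], z[-1, 0], z[-1, -1] = rng.normal(0, 1, 4)
    step = n
    amp = 1.0
    while step > 1:
        half = step // 2
        # diamond step
        for r in range(half, side, step):
            for c in range(half, side, step):
                avg = (
                    z[r - half, c - half]
                    + z[r - half, c + half]
                    + z[r + half, c - half]
                    + z[r + half, c + half]
                ) / 4.0
                z[r, c] = avg + rng.normal(0, amp)
        # square step
        for r in range(0, side, half):
            start = half if (r // half) % 2 == 0 else 0
            for c in range(start, side, step):
                total, cnt = 0.0, 0
                for dr, dc in ((-half, 0), (half, 0), (0, -half), (0, half)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < side and 0 <= cc < side:
                        total += z[rr, cc]
                        cnt += 1
                z[r, c] = total / cnt + rng.normal(0, amp)
        step = half
        amp *= roughness
    return z


def random_terrain_scene(
    nrows: int = 60,
    ncols: int = 60,
    seed: int = 42,
    n_regions: int = 12,
    roughness: float = 0.55,
    margin: int = 2,
) -> SyntheticScene:
    """Seeded fractal island terrain with Voronoi villages and an
    oracle-computed expected table (the end-to-end regression fixture)."""
    if n_regions < 1:
        raise ParameterError("n_regions must be >= 1")
    if nrows * ncols > 10_000:
        raise ParameterError(
            "random_terrain_scene is oracle-verified and limited to 10,000 cells"
        )
    rng = np.random.default_rng(seed)
    z = _midpoint_displacement(max(nrows, ncols), rng, roughness)[:nrows, :ncols]
    span = float(z.max() - z.min())
    z = (z - z.min()) / (span if span > 0 else 1.0) * 100.0
    values = z + 1.0  # strictly positive land elevations
    values[:margin, :] = NODATA
    values[-margin:, :] = NODATA
    values[:, :margin] = NODATA
    values[:, -margin:] = NODATA
    grid = RasterGrid(
        values=values,
        origin_x=0.0,
        origin_y=nrows * CELL,
        cell_size=CELL,
        nodata=NODATA,
    )
    land = np.argwhere(grid.valid_mask())
    if len(land) < n_regions:
        raise ParameterError("not enough land cells for the requested regions")
    seed_idx = rng.choice(len(land), size=n_regions, replace=False)
    seeds = land[np.sort(seed_idx)]
    # Voronoi labels over land cells (ties -> smaller seed index)
    d2 = ((land[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    owner = d2.argmin(axis=1)
    ids = [_region_label("R", k, n_regions) for k in range(n_regions)]
    records = []
    for k, rid in enumerate(ids):
        cells = [tuple(rc) for rc in land[owner == k]]
        records.append(RegionRecord(rid, _cells_to_polygon(cells, grid)))
    regions = RegionSet(records)

    # ground truth through the oracle path (brute-force watershed walking)
    partition = classify_nodata(grid)
    conditioned = fill_depressions(fill_voids(grid, partition), ocean=partition)
    dirs = flow_direction(conditioned, ocean=classify_nodata(conditioned))
    acc = flow_accumulation(dirs)
    labels = rasterize(regions, grid)
    pour_points = place_pour_points(labels, acc)
    entries = {
        p.region_id: extract_upstream(labels, oracle_delineate(dirs, p), p.region_id)
        for p in pour_points
    }
    expected = UpstreamTable(entries=entries)
    return SyntheticScene(
        grid=grid,
        regions=regions,
        expected=expected,
        seed=seed,
        descriptor={
            "scene": "random",
            "nrows": nrows,
            "ncols": ncols,
            "n_regions": n_regions,
            "roughness": roughness,
            "margin": margin,
        },
    )
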