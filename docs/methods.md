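# Methods

## Problem and model

The package computes, for each region polygon over a digital elevation
model, the set of all other regions intersecting its upstream drainage
area. The hydrological model is the standard terrestrial single-flow-
direction abstraction:

- Terrain is a square-cell raster in a projected metric CRS; the sea and
  anything off-grid are drainage targets.
- Every land cell drains to exactly one of its eight neighbors (D8), the
  one maximizing (elevation drop)/(distance), with distance 1 for cardinal
  and √2 for diagonal steps in cell units. A cell with no strictly lower
  land neighbor must touch ocean or the grid border; it is an outlet.
- The upstream area (watershed) of a cell is the set of cells whose D8
  paths pass through it. A region's watershed is delineated from its *pour
  point*, the maximum-flow-accumulation cell inside the region — placing it
  anywhere else could miss an entire river entering the region.
- The upstream table lists, per focal region, every other region with at
  least one raster cell inside the focal watershed. Membership is binary;
  one cell suffices ("wholly or partially contained"). A region never lists
  itself.

Assumptions worth stating: flow is overland and unweighted (no rainfall or
infiltration model); routing is single-direction, so divergent flow over
flats and fans is collapsed onto one path; region membership is decided at
the raster resolution, so polygons thinner than a cell can drop out (they
are reported, not silently lost).

## Pipeline stages and numerical choices

**Mosaicking and aggregation.** Tiles must be grid-aligned; overlapping
cells must agree, and disagreement is an error rather than a silent
overwrite. Block aggregation to a coarser analysis resolution uses the
nodata-aware block mean — the conventional DEM downsampling statistic —
and averages partial edge blocks over the cells they have, so no terrain
is dropped. On fully valid integer grids whose dimensions divide by the
factor, the block mean conserves the grid sum exactly (scaled by factor²),
which the tests pin down.

**Ocean vs voids.** Nodata 4-connected to the grid border is ocean; the
rest are interior voids. 4-connectivity is deliberate: a diagonal chain of
nodata does not connect an inland lake to the sea, so no phantom inlets are
created. An explicit ocean mask can override the rule for grids whose true
coastline is not border-connected.

**Void filling.** Voids are filled by solving the discrete Laplace equation
over the void cells with the surrounding valid cells as Dirichlet boundary
(Jacobi iteration, convergence threshold 1e-6 m). Harmonic interpolation
reproduces affine surfaces exactly — the property that matters for drainage
directions across a hole — and obeys the maximum principle, so filled
values cannot overshoot the rim; they are clamped to the rim's range as a
second guarantee. Filling is idempotent. Voids larger than 10,000 cells
abort rather than extrapolate an invented landscape. This interpolant was
chosen over spline fitting because it is deterministic, dependency-light,
and its one load-bearing property (linear exactness) is testable.

**Depression filling.** Priority-flood with an epsilon gradient: land cells
adjacent to ocean or the border seed a priority queue at their own
elevation; cells are popped in ascending (elevation, row, col) order and
each newly reached neighbor is raised to at least popped + ε. Default
ε = 0.001 m — small enough to be invisible against meter-scale relief,
large enough to be robust in float64 across any realistic DEM magnitude.
The (row, col) tie-break makes the output bit-identical across runs. The
postcondition downstream stages rely on is exactly: every land cell has a
strictly lower 8-neighbor or touches ocean/border, which chains to a
strictly descending path to an outlet.

**Flow routing.** Ties on the steepest weighted drop are broken by the
fixed neighbor precedence E, SE, S, SW, W, NW, N, NE (first maximal drop
wins). Direction codes use the power-of-two encoding (1=E … 128=NE, 0 =
outlet). Accumulation is self-inclusive (minimum 1) — the convention that
makes the inclusive arithmetic-series bound internally consistent — and is
computed by Kahn's algorithm over the pointer forest in linear time, which
also detects any cycle a corrupted pointer file could introduce.

**Rasterization and pour points.** Cell-center-in-polygon labelling
(standard zonal-statistics semantics). Residual overlaps are resolved by:
interior containment beats boundary contact, then smaller polygon area
(enclaves beat their host), then lexicographically smaller id; a center
exactly on a shared edge therefore goes to the smaller id. Pour-point ties
on the zonal maximum go to the smallest (row, col). All three rules exist
only to make the output deterministic; they affect single boundary cells.

**Delineation and table assembly.** Delineation is reverse-flow BFS; the
test oracle forward-walks every cell's path instead and is size-guarded to
10,000 cells. Watershed masks live only in memory — at national scale,
writing hundreds of thousands of polygon watersheds dominates runtime and
storage, while the final table is tiny. Per-region tasks are pure functions
of the shared direction and label grids, run serially or on a process pool;
results are keyed by region id, so the table is identical for any worker
count. A failed task is retried once and then recorded in the run report.
The CSV dialect is deliberately minimal: focal id, comma, upstream ids,
sorted by focal id; shard merging refuses duplicate focal ids.

## Theoretical bounds: two conventions

The linear-river maximum can be written per-village-inclusive,
n(n+1)/2, or exclusive, n(n−1)/2; they differ by exactly n. The headline
bounds published for this tool's original national use case follow the
inclusive form (each village counted once for itself), while the emitted
table is exclusive ("all *other* villages"). Both are implemented;
`theoretical_max` defaults to inclusive to reproduce the published values,
and the table's realized chain-scene total matches the exclusive form.

## What the synthetic scenes emulate — and what they do not

- `linear_chain_scene`: the maximal thought experiment — one monotone
  1-cell river, n consecutive villages; expected lists of length 0…n−1.
- `cone_island_scene`: the minimal thought experiment — shoreline villages
  around a conical island, all expected lists empty. The cone's contours
  are Chebyshev-metric squares rather than Euclidean circles: under D8 a
  Euclidean cone develops along-shore drift (a shore cell can have a
  marginally lower shore neighbor), which would leak flow between
  shoreline villages and destroy the scenario's defining property. With
  square contours every shoreline cell is an outlet and descent is exactly
  radial, so "zero relations" holds by construction rather than by luck.
- `confluence_scene`: a Y-shaped valley; the trunk village must list both
  headwater arms — the case that motivates maximum-accumulation pour
  points.
- `random_terrain_scene`: seeded midpoint-displacement (diamond-square)
  terrain, roughness 0.55, a 2-cell ocean margin, and Voronoi villages
  around seeded land cells; its expected table is computed through the
  brute-force oracle, never the production traversal, making it the
  end-to-end regression fixture. Scene generation is bit-reproducible from
  (seed, parameters).

The scenes exercise the pipeline's logic, not real-sensor pathology: they
contain no canopy-height artifacts, no correlated radar voids, no
geolocation noise, and their villages tile the land cleanly. Passing tests
therefore demonstrate algorithmic correctness on well-posed terrain, not
robustness to a particular elevation product's error structure.

## Problem sizes used in the tests

Property suites run on seeded synthetic islands: depression-filling
drainage is verified on 200 terrains of 60×60 cells; accumulation against
the path-walking oracle on 50×50 terrains; delineation against the oracle,
plus the partition and nesting properties, on 100 terrains of 40×40; the
end-to-end fixtures use 10 chain villages, a radius-20 cone with 8
shoreline villages, arm-length-5 confluence, and a 60×60 random island
with 12 villages. These sizes give full coverage of every code path and
invariant while keeping the whole suite near ten seconds.

## Known limitations

- Single-direction D8 only; no D-infinity or multiple-flow-direction
  routing, no stream-burning against a mapped river network.
- Depressions are filled, not carved; real closed basins (volcanic lakes)
  are forced to drain.
- Geographic-to-projected reprojection is out of scope: inputs must
  already be metric, and degree-like cell sizes only trigger a warning.
- Shapefile input is not supported; convert to GeoJSON first.
- Binary region membership: a village 1% inside a watershed counts the
  same as one wholly inside. Overlap-fraction weighting would require an
  area model the upstream-exposure use case has not needed.
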