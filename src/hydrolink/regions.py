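"""Region polygons (villages): reading, validation, rasterization, pour points.

The survey polygons this tool was designed around arrive with only a unique
identifier per region — all other attributes are dropped on read. Geometries
are repaired (made valid), exact duplicate records are deduplicated, and a
duplicated id with a *different* geometry is an error.

Rasterization uses the cell-center rule: a cell belongs to the region whose
polygon contains its center. A center strictly inside several overlapping
regions goes to the smaller-area region (enclaves win over their host); a
center exactly on a shared boundary goes to the lexicographically smallest
region id. Regions that capture no cell at all (slivers thinner than a cell)
are not fatal — they are listed in a skip report so totals reconcile.

The pour point of a region is its cell of maximum flow accumulation (zonal
maximum), ties broken by (row, col) ascending.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry

from .errors import (
    DuplicateIdError,
    EmptyInputError,
    GridFormatError,
    UnsupportedInputError,
)
from .grid import RasterGrid
from .routing import FlowAccumulationGrid

BACKGROUND = -1


@dataclass
class RegionRecord:
    region_id: str
    geometry: BaseGeometry


@dataclass
class RegionSet:
    """Identified, repaired polygons in the raster's coordinate system."""

    records: list[RegionRecord]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate region ids: {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.region_id for r in self.records]

    def get(self, region_id: str) -> RegionRecord:
        for r in self.records:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)


@dataclass
class RegionLabelGrid:
    """Rasterized regions: ``labels[r, c]`` indexes into ``region_ids``
    (BACKGROUND = no region); georeference as the template raster."""

    labels: np.ndarray
    region_ids: list[str]
    origin_x: float
    origin_y: float
    cell_size: float
    skipped: list[str] = field(default_factory=list)  # regions with zero cells

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def id_at(self, row: int, col: int) -> str | None:
        idx = int(self.labels[row, col])
        return None if idx == BACKGROUND else self.region_ids[idx]

    def cells_of(self, region_id: str) -> list[tuple[int, int]]:
        idx = self.region_ids.index(region_id)
        return [tuple(rc) for rc in np.argwhere(self.labels == idx)]


@dataclass(frozen=True)
class PourPoint:
    """The outlet cell of a region: its maximum-flow-accumulation cell."""

    region_id: str
    row: int
    col: int
    accumulation: int


def read_regions(path: str | Path, id_field: str) -> RegionSet:
    """Read region polygons from GeoJSON, keeping only the id attribute.

    Invalid geometries are repaired with ``shapely.make_valid``; rows sharing
    an id with identical geometry collapse to one record; rows sharing an id
    with different geometries raise :class:`DuplicateIdError`.
    """
    path = Path(path)
    if path.suffix.lower() in {".shp", ".shx", ".dbf"}:
        raise UnsupportedInputError(
            f"{path}: shapefile input is not supported; convert to GeoJSON"
        )
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise GridFormatError(f"{path}: not readable GeoJSON ({exc})") from exc
    features = doc.get("features", [])
    if not features:
        raise EmptyInputError(f"{path}: GeoJSON contains no features")
    by_id: dict[str, BaseGeometry] = {}
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        if id_field not in props:
            raise GridFormatError(
                f"{path}: feature {i} is missing id field {id_field!r}"
            )
        rid = str(props[id_field])
        geom = geojson_shape(feat["geometry"])
        if geom.geom_type not in {"Polygon", "MultiPolygon"}:
            raise UnsupportedInputError(
                f"{path}: feature {i} has geometry type {geom.geom_type}; "
                "polygons required"
            )
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        if rid in by_id:
            if by_id[rid].equals(geom):
                continue  # exact duplicate row — drop it
            raise DuplicateIdError(
                f"{path}: id {rid!r} appears with two different geometries"
            )
        by_id[rid] = geom
    return RegionSet([RegionRecord(rid, g) for rid, g in by_id.items()])


def write_regions(regions: RegionSet, path: str | Path, id_field: str = "region_id") -> Path:
    """Write a RegionSet back to GeoJSON (used by the synthetic scenes)."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {id_field: rec.region_id},
            "geometry": json.loads(shapely.to_geojson(rec.geometry)),
        }
        for rec in regions
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


def overlap_report(
    regions: RegionSet, tolerance_fraction: float = 0.01
) -> list[tuple[str, str, float]]:
    """Pairs of regions whose interiors overlap by more than
    ``tolerance_fraction`` of the smaller region's area."""
    out = []
    recs = regions.records
    tree = shapely.STRtree([r.geometry for r in recs])
    for i, rec in enumerate(recs):
        for j in tree.query(rec.geometry, predicate="intersects"):
            if j <= i:
                continue
            other = recs[j]
            inter = rec.geometry.intersection(other.geometry).area
            smaller = min(rec.geometry.area, other.geometry.area)
            if smaller > 0 and inter / smaller > tolerance_fraction:
                out.append((rec.region_id, other.region_id, inter / smaller))
    return out


def rasterize(regions: RegionSet, template: RasterGrid) -> RegionLabelGrid:
    """Label each cell of ``template`` with the region containing its center.

    Conflict resolution, in order: a center strictly inside a polygon beats
    one merely on its boundary; then smaller polygon area; then smaller id.
    """
    nrows, ncols = template.shape
    labels = np.full((nrows, ncols), BACKGROUND, dtype=np.int32)
    region_ids = [rec.region_id for rec in regions]
    # claim[r, c] = (0 interior / 1 boundary, area, region_id, index)
    claims: dict[tuple[int, int], tuple[int, float, str, int]] = {}
    cs = template.cell_size
    for idx, rec in enumerate(regions):
        minx, miny, maxx, maxy = rec.geometry.bounds
        c0 = max(0, int(np.floor((minx - template.origin_x) / cs - 0.5)))
        c1 = min(ncols - 1, int(np.ceil((maxx - template.origin_x) / cs)))
        r0 = max(0, int(np.floor((template.origin_y - maxy) / cs - 0.5)))
        r1 = min(nrows - 1, int(np.ceil((template.origin_y - miny) / cs)))
        if c1 < c0 or r1 < r0:
            continue
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        cc, rr = np.meshgrid(cols, rows)
        xs = template.origin_x + (cc + 0.5) * cs
        ys = template.origin_y - (rr + 0.5) * cs
        inside = shapely.contains_xy(rec.geometry, xs.ravel(), ys.ravel())
        touching = shapely.intersects_xy(rec.geometry, xs.ravel(), ys.ravel())
        area = rec.geometry.area
        for flat in np.nonzero(touching)[0]:
            cell = (int(rr.ravel()[flat]), int(cc.ravel()[flat]))
            # interior containment beats boundary contact; interior conflicts
            # go to the smaller area, boundary ties to the smaller id
            claim = (
                (0, area, rec.region_id, idx)
                if inside[flat]
                else (1, 0.0, rec.region_id, idx)
            )
            prev = claims.get(cell)
            if prev is None or claim[:3] < prev[:3]:
                claims[cell] = claim
    for (r, c), (_, _, _, idx) in claims.items():
        labels[r, c] = idx
    covered = set(np.unique(labels)) - {BACKGROUND}
    skipped = [rid for i, rid in enumerate(region_ids) if i not in covered]
    return RegionLabelGrid(
        labels=labels,
        region_ids=region_ids,
        origin_x=template.origin_x,
        origin_y=template.origin_y,
        cell_size=template.cell_size,
        skipped=skipped,
    )


def place_pour_points(
    labels: RegionLabelGrid, acc: FlowAccumulationGrid
) -> list[PourPoint]:
    """One pour point per labelled region, on its zonal-maximum accumulation
    cell; ties broken by (row, col) ascending. Returned sorted by region id."""
    if labels.shape != acc.shape:
        raise GridFormatError(
            f"label grid {labels.shape} and accumulation grid {acc.shape} differ"
        )
    best: dict[int, tuple[int, int, int]] = {}  # idx -> (acc, row, col)
    nrows, ncols = labels.shape
    lab = labels.labels
    counts = acc.counts
    for r in range(nrows):
        for c in range(ncols):
            idx = lab[r, c]
            if idx == BACKGROUND:
                continue
            a = int(counts[r, c])
            if a < 1:  # labelled cell lying over ocean carries no flow
                continue
            cur = best.get(idx)
            if cur is None or a > cur[0]:
                best[idx] = (a, r, c)
    points = [
        PourPoint(
            region_id=labels.region_ids[idx], row=rw, col=cl, accumulation=a
        )
        for idx, (a, rw, cl) in best.items()
    ]
    return sorted(points, key=lambda p: p.region_id)
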