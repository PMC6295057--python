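"""Region reading/repair, cell-center rasterization, pour-point placement."""

import json

import numpy as np
import pytest
from shapely.geometry import box, mapping

from hydrolink import place_pour_points, rasterize, read_regions
from hydrolink.errors import DuplicateIdError, EmptyInputError, GridFormatError
from hydrolink.regions import BACKGROUND, RegionRecord, RegionSet
from hydrolink.routing import FlowAccumulationGrid

from conftest import make_grid


def geojson(tmp_path, features, name="regions.geojson"):
    path = tmp_path / name
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def feature(region_id, geom, id_field="desa_id"):
    return {
        "type": "Feature",
        "properties": {id_field: region_id},
        "geometry": mapping(geom),
    }


def acc_grid(counts, cell=90.0):
    counts = np.asarray(counts)
    return FlowAccumulationGrid(
        counts=counts,
        origin_x=0.0,
        origin_y=counts.shape[0] * cell,
        cell_size=cell,
    )


class TestReadRegions:
    def test_reads_rectangles_keeping_only_the_id(self, tmp_path):
        feats = [
            feature(rid, box(i * 100, 0, i * 100 + 90, 90))
            for i, rid in enumerate("ABC")
        ]
        regions = read_regions(geojson(tmp_path, feats), "desa_id")
        assert sorted(regions.ids()) == ["A", "B", "C"]

    def test_identical_duplicate_rows_collapse(self, tmp_path):
        geom = box(0, 0, 90, 90)
        regions = read_regions(
            geojson(tmp_path, [feature("A", geom), feature("A", geom)]), "desa_id"
        )
        assert len(regions) == 1

    def test_same_id_different_geometry_is_an_error(self, tmp_path):
        path = geojson(
            tmp_path,
            [feature("A", box(0, 0, 90, 90)), feature("A", box(0, 0, 90, 180))],
        )
        with pytest.raises(DuplicateIdError):
            read_regions(path, "desa_id")

    def test_missing_id_field_and_empty_file_raise(self, tmp_path):
        path = geojson(tmp_path, [feature("A", box(0, 0, 90, 90), id_field="other")])
        with pytest.raises(GridFormatError, match="desa_id"):
            read_regions(path, "desa_id")
        with pytest.raises(EmptyInputError):
            read_regions(geojson(tmp_path, [], name="empty.geojson"), "desa_id")

    def test_self_intersecting_polygon_is_repaired(self, tmp_path):
        bowtie = {
            "type": "Feature",
            "properties": {"desa_id": "A"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[0, 0], [90, 90], [90, 0], [0, 90], [0, 0]]],
            },
        }
        regions = read_regions(geojson(tmp_path, [bowtie]), "desa_id")
        assert regions.records[0].geometry.is_valid


class TestRasterize:
    def test_rectangle_covering_a_2x3_block(self):
        template = make_grid(np.zeros((4, 5)))
        # covers cell centers of rows 1-2, cols 1-3 exactly
        regions = RegionSet([RegionRecord("A", box(90, 90, 360, 270))])
        labels = rasterize(regions, template)
        assert (labels.labels != BACKGROUND).sum() == 6
        assert labels.id_at(1, 1) == "A" and labels.id_at(2, 3) == "A"

    def test_sliver_with_no_center_appears_in_skip_report(self):
        template = make_grid(np.zeros((3, 3)))
        sliver = box(100, 0, 120, 270)  # thinner than a cell, misses all centers
        labels = rasterize(RegionSet([RegionRecord("S", sliver)]), template)
        assert (labels.labels == BACKGROUND).all()
        assert labels.skipped == ["S"]

    def test_center_on_shared_edge_goes_to_lexicographically_smaller_id(self):
        template = make_grid(np.zeros((1, 1)), cell_size=90.0)
        # both rectangles end exactly at the cell center x = 45
        left = RegionRecord("B", box(0, 0, 45, 90))
        right = RegionRecord("A", box(45, 0, 90, 90))
        labels = rasterize(RegionSet([left, right]), template)
        assert labels.id_at(0, 0) == "A"

    def test_interior_overlap_goes_to_the_smaller_region(self):
        template = make_grid(np.zeros((2, 2)))
        big = RegionRecord("A", box(0, 0, 180, 180))
        small = RegionRecord("Z", box(0, 90, 90, 180))  # covers cell (0, 0) only
        labels = rasterize(RegionSet([big, small]), template)
        assert labels.id_at(0, 0) == "Z"
        assert labels.id_at(1, 1) == "A"

    def test_cell_counts_stable_under_record_order(self):
        template = make_grid(np.zeros((4, 4)))
        a = RegionRecord("A", box(0, 0, 180, 360))
        b = RegionRecord("B", box(180, 0, 360, 360))
        l1 = rasterize(RegionSet([a, b]), template)
        l2 = rasterize(RegionSet([b, a]), template)
        for rid in ("A", "B"):
            assert sorted(l1.cells_of(rid)) == sorted(l2.cells_of(rid))


class TestPourPoints:
    def test_pour_point_on_the_zonal_maximum(self):
        template = make_grid(np.zeros((1, 3)))
        labels = rasterize(
            RegionSet([RegionRecord("A", box(0, 0, 270, 90))]), template
        )
        acc = acc_grid([[3, 9, 7]])
        (p,) = place_pour_points(labels, acc)
        assert (p.row, p.col, p.accumulation) == (0, 1, 9)

    def test_pour_point_sits_on_the_most_downstream_covered_cell(self, ramp_1x5):
        from conftest import route

        _, _, acc = route(ramp_1x5)
        template = ramp_1x5
        # village covers the ramp cells with accumulation 2 and 3
        region = RegionSet([RegionRecord("V", box(90, 90, 270, 180))])
        labels = rasterize(region, template)
        (p,) = place_pour_points(labels, acc)
        assert p.accumulation == 3

    def test_tie_broken_by_row_then_col(self):
        counts = np.ones((5, 8), dtype=int)
        counts[4, 2] = 9
        counts[2, 7] = 9
        template = make_grid(np.zeros((5, 8)))
        labels = rasterize(
            RegionSet([RegionRecord("A", box(0, 0, 720, 450))]), template
        )
        (p,) = place_pour_points(labels, acc_grid(counts))
        assert (p.row, p.col) == (2, 7)

    def test_accumulation_equals_brute_force_zonal_max(self, random_scene):
        from conftest import route

        _, _, acc = route(random_scene.grid)
        labels = rasterize(random_scene.regions, random_scene.grid)
        points = place_pour_points(labels, acc)
        assert points  # at least one region carries flow
        for p in points:
            cells = labels.cells_of(p.region_id)
            assert p.accumulation == max(int(acc.counts[r, c]) for r, c in cells)
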