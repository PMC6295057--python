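"""Raster container, file round-trips, mosaicking, block aggregation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrolink import RasterGrid, aggregate, mosaic, read_grid, write_grid
from hydrolink.errors import (
    AlignmentError,
    GridFormatError,
    GridInvariantError,
    MosaicConflictError,
    ParameterError,
    UnsupportedInputError,
)

from conftest import make_grid, NODATA


@pytest.mark.parametrize("ext,fmt", [(".tif", "geotiff"), (".asc", "ascii_grid")])
def test_write_read_round_trip_is_bit_exact(tmp_path, ext, fmt):
    grid = make_grid(
        [[1.25, 2.0, NODATA], [3.5, NODATA, 4.75]],
        origin_x=1234.5,
    )
    grid.crs_tag = "ESRI:54009"
    path = tmp_path / f"g{ext}"
    write_grid(grid, path, format=fmt)
    back = read_grid(path, format=fmt)
    np.testing.assert_array_equal(back.values, grid.values)
    assert back.origin_x == grid.origin_x
    assert back.origin_y == grid.origin_y
    assert back.cell_size == grid.cell_size
    assert back.nodata == grid.nodata
    if fmt == "geotiff":  # the ASCII header has no CRS slot
        assert back.crs_tag == grid.crs_tag


def test_ascii_grid_parses_values_and_georeference(tmp_path):
    path = tmp_path / "g.asc"
    path.write_text(
        "NCOLS 2\nNROWS 2\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 90\n"
        "NODATA_VALUE -9999\n1 2\n3 4\n"
    )
    grid = read_grid(path)
    assert grid.values[0].tolist() == [1.0, 2.0]
    assert grid.origin_y == 180.0  # yllcorner + nrows * cellsize
    assert grid.cell_center(0, 0) == (45.0, 135.0)


def test_nodata_cell_round_trips_as_nodata(tmp_path):
    grid = make_grid([[NODATA, 2.0], [3.0, 4.0]])
    back = read_grid(write_grid(grid, tmp_path / "g.asc"))
    assert not back.valid_mask()[0, 0]


def test_all_nodata_row_survives_round_trip(tmp_path):
    grid = make_grid([[NODATA, NODATA], [1.0, 2.0]])
    back = read_grid(write_grid(grid, tmp_path / "g.tif"))
    np.testing.assert_array_equal(back.values, grid.values)


def test_garbled_file_raises_format_error_with_location(tmp_path):
    bad = tmp_path / "bad.asc"
    bad.write_text("NCOLS 2\nNROWS 1\nXLLCORNER 0\nYLLCORNER 0\nCELLSIZE 90\n1 x\n")
    with pytest.raises(GridFormatError, match="line"):
        read_grid(bad)
    with pytest.raises(GridFormatError):
        read_grid(tmp_path / "missing.tif")


def test_multiband_tiff_is_rejected(tmp_path):
    import tifffile

    path = tmp_path / "rgb.tif"
    tifffile.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8), photometric="rgb")
    with pytest.raises(UnsupportedInputError, match="band"):
        read_grid(path)


def test_invalid_cell_size_rejected_before_write(tmp_path):
    with pytest.raises(GridInvariantError):
        RasterGrid(values=np.ones((2, 2)), origin_x=0, origin_y=180, cell_size=0)


def test_degree_like_cell_size_warns_but_does_not_fail():
    with pytest.warns(UserWarning, match="geographic"):
        make_grid([[1.0]], cell_size=0.0008333)


class TestMosaic:
    def test_two_adjacent_tiles_merge_seamlessly(self):
        west = make_grid([[1, 2], [3, 4]], origin_x=0)
        east = make_grid([[5, 6], [7, 8]], origin_x=180)
        merged = mosaic([west, east])
        assert merged.values.tolist() == [[1, 2, 5, 6], [3, 4, 7, 8]]
        assert merged.origin_x == 0 and merged.origin_y == 180

    def test_single_tile_returned_unchanged(self):
        tile = make_grid([[1, 2], [3, 4]])
        merged = mosaic([tile])
        np.testing.assert_array_equal(merged.values, tile.values)
        assert merged.origin_x == tile.origin_x

    def test_gap_between_tiles_becomes_nodata(self):
        west = make_grid([[1.0]], origin_x=0)
        east = make_grid([[2.0]], origin_x=180)
        merged = mosaic([west, east])
        assert merged.values.tolist() == [[1.0, NODATA, 2.0]]

    def test_conflicting_overlap_is_an_error_naming_the_cell(self):
        a = make_grid([[5.0]])
        b = make_grid([[7.0]])
        with pytest.raises(MosaicConflictError, match=r"\(0, 0\)"):
            mosaic([a, b])

    def test_agreeing_overlap_is_kept(self):
        a = make_grid([[5.0, 6.0]])
        b = make_grid([[6.0, 7.0]], origin_x=90)
        assert mosaic([a, b]).values.tolist() == [[5.0, 6.0, 7.0]]

    def test_misaligned_origin_rejected(self):
        a = make_grid([[1.0]], origin_x=0)
        b = make_grid([[2.0]], origin_x=45)  # half a cell off
        with pytest.raises(AlignmentError):
            mosaic([a, b])

    def test_order_invariance_over_all_permutations(self):
        tiles = [
            make_grid([[1, 2]], origin_x=0, origin_y=90),
            make_grid([[3, 4]], origin_x=180, origin_y=90),
            make_grid([[5, 6]], origin_x=0, origin_y=180),
        ]
        reference = mosaic(tiles)
        for perm in itertools.permutations(tiles):
            np.testing.assert_array_equal(mosaic(list(perm)).values, reference.values)


class TestAggregate:
    def test_uniform_blocks_average_to_the_same_value(self):
        grid = make_grid(np.ones((6, 6)))
        out = aggregate(grid, 3)
        assert out.shape == (2, 2)
        assert np.all(out.values == 1.0)
        assert out.cell_size == 270.0

    def test_mean_of_full_block(self):
        grid = make_grid(np.arange(1, 10, dtype=float).reshape(3, 3))
        assert aggregate(grid, 3).values.tolist() == [[5.0]]

    def test_nodata_aware_mean_uses_only_valid_cells(self):
        grid = make_grid([[10.0, NODATA], [NODATA, 14.0]])
        assert aggregate(grid, 2).values.tolist() == [[12.0]]

    def test_all_nodata_block_stays_nodata(self):
        grid = make_grid([[NODATA, NODATA], [NODATA, 1.0]])
        out = aggregate(make_grid(np.full((4, 4), NODATA)), 2)
        assert np.all(out.values == NODATA)

    def test_partial_edge_blocks_are_averaged_not_dropped(self):
        grid = make_grid([[1.0, 2.0, 30.0]])
        out = aggregate(grid, 2)
        assert out.values.tolist() == [[1.5, 30.0]]

    def test_factor_one_is_identity(self):
        grid = make_grid([[1.0, NODATA], [3.0, 4.0]])
        np.testing.assert_array_equal(aggregate(grid, 1).values, grid.values)

    def test_bad_factor_rejected(self):
        with pytest.raises(ParameterError):
            aggregate(make_grid([[1.0]]), 0)

    @settings(derandomize=True, max_examples=25)
    @given(
        factor=st.integers(1, 4),
        blocks_r=st.integers(1, 3),
        blocks_c=st.integers(1, 3),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_sum_conservation_on_fully_valid_integer_grids(
        self, factor, blocks_r, blocks_c, seed
    ):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 50, size=(blocks_r * factor, blocks_c * factor))
        grid = make_grid(vals.astype(float))
        out = aggregate(grid, factor)
        assert out.values.sum() * factor**2 == vals.sum()
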