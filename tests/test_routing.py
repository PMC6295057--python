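"""D8 flow directions and accumulation, checked against path-walking oracles."""

import math

import numpy as np
import pytest

from hydrolink import flow_accumulation, flow_direction
from hydrolink.errors import CorruptedDirectionError, UnconditionedInputError
from hydrolink.routing import DIR_NODATA, OUTLET, FlowDirectionGrid

from conftest import make_grid, random_island, route, NODATA

E, SE, S, SW, W, NW, N, NE = 1, 2, 4, 8, 16, 32, 64, 128


def brute_force_accumulation(dirs: FlowDirectionGrid) -> np.ndarray:
    """Oracle: for every cell walk its D8 path, incrementing every visited
    cell (including the start)."""
    nrows, ncols = dirs.shape
    counts = np.where(dirs.land_mask(), 0, -1).astype(int)
    for r in range(nrows):
        for c in range(ncols):
            if dirs.codes[r, c] == DIR_NODATA:
                continue
            cur = (r, c)
            while cur is not None:
                counts[cur] += 1
                cur = dirs.downstream(*cur)
    return counts


def test_east_ramp_points_east_with_terminal_outlet(ramp_1x5):
    dirs = flow_direction(ramp_1x5)
    assert dirs.codes[1].tolist() == [E, E, E, E, OUTLET]
    assert np.all(dirs.codes[0] == DIR_NODATA)


def test_distance_weighting_prefers_cardinal_over_slightly_deeper_diagonal():
    # drop 1.0 east (distance 1) beats drop 1.4 southeast (distance sqrt 2):
    # 1.0/1 > 1.4/1.414
    vals = np.full((3, 3), 10.0)
    vals[1, 2] = 9.0  # east of center
    vals[2, 2] = 8.6  # southeast of center
    grid = make_grid(vals)
    dirs = flow_direction(grid)
    assert dirs.codes[1, 1] == E
    assert 1.0 / 1.0 > 1.4 / math.sqrt(2.0)  # the arithmetic being encoded


def test_tie_on_equal_weighted_drop_follows_the_fixed_precedence():
    vals = np.full((3, 3), 10.0)
    vals[1, 2] = 9.0  # E, drop 1
    vals[2, 1] = 9.0  # S, drop 1 — E precedes S
    assert flow_direction(make_grid(vals)).codes[1, 1] == E


def test_cone_island_routes_all_paths_to_outlets(cone_scene):
    _, dirs, _ = route(cone_scene.grid)
    land = dirs.land_mask()
    nrows, ncols = dirs.shape
    # every shoreline cell (land touching ocean) is an outlet
    for r in range(nrows):
        for c in range(ncols):
            if not land[r, c]:
                continue
            coastal = any(
                not land[r + dr, c + dc]
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)
            )
            if coastal:
                assert dirs.codes[r, c] == OUTLET
    # every path terminates at an outlet within the cell budget
    for r, c in np.argwhere(land):
        cur, steps = (int(r), int(c)), 0
        while dirs.codes[cur] != OUTLET:
            cur = dirs.downstream(*cur)
            steps += 1
            assert steps <= nrows * ncols
        assert dirs.codes[cur] == OUTLET


def test_unconditioned_pit_raises_naming_the_cell():
    vals = np.full((5, 5), 5.0)
    vals[2, 2] = 1.0  # interior pit, not conditioned
    with pytest.raises(UnconditionedInputError, match=r"\(2, 2\)"):
        flow_direction(make_grid(vals))


class TestAccumulation:
    def test_east_chain_counts_increase_downstream(self, ramp_1x5):
        dirs = flow_direction(ramp_1x5)
        acc = flow_accumulation(dirs)
        assert acc.counts[1].tolist() == [1, 2, 3, 4, 5]

    def test_two_chains_converging_sum_at_the_junction(self):
        # two 3-cell chains (one from the west, one from the north) draining
        # into one junction cell: the junction counts 3 + 3 + 1 = 7
        vals = np.full((6, 6), NODATA)
        vals[3, 0:3] = [12, 11, 10]  # west chain, flows east
        vals[0:3, 3] = [12, 11, 10]  # north chain, flows south
        vals[3, 3] = 9.0  # junction
        grid = make_grid(vals)
        dirs = flow_direction(grid)
        acc = flow_accumulation(dirs)
        assert acc.counts[3, 3] == 7

    def test_all_outlet_grid_counts_one_everywhere(self):
        codes = np.zeros((3, 3), dtype=np.int16)
        dirs = FlowDirectionGrid(codes=codes, origin_x=0, origin_y=270, cell_size=90)
        assert np.all(flow_accumulation(dirs).counts == 1)

    def test_single_outlet_island_conserves_the_cell_count(self, chain_scene):
        _, dirs, acc = route(chain_scene.grid)
        land = dirs.land_mask()
        outlets = np.argwhere((dirs.codes == 0))
        assert len(outlets) == 1
        assert acc.counts[tuple(outlets[0])] == land.sum()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_path_walk_on_random_terrain(self, seed):
        _, dirs, acc = route(random_island(30, 40, seed=seed))
        np.testing.assert_array_equal(acc.counts, brute_force_accumulation(dirs))

    def test_sum_identity_total_equals_total_path_length(self):
        _, dirs, acc = route(random_island(20, 20, seed=8))
        total_path = 0
        for r, c in np.argwhere(dirs.land_mask()):
            cur = (int(r), int(c))
            while cur is not None:
                total_path += 1
                cur = dirs.downstream(*cur)
        assert acc.counts[acc.counts > 0].sum() == total_path

    def test_cycle_is_detected(self):
        codes = np.full((1, 2), DIR_NODATA, dtype=np.int16)
        codes[0, 0] = E
        codes[0, 1] = W
        dirs = FlowDirectionGrid(codes=codes, origin_x=0, origin_y=90, cell_size=90)
        with pytest.raises(CorruptedDirectionError, match="cycle"):
            flow_accumulation(dirs)
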