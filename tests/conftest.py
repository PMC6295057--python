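"""Shared fixtures: tiny hand-drawn grids and the synthetic scenes."""

import numpy as np
import pytest

from hydrolink import (
    RasterGrid,
    classify_nodata,
    fill_depressions,
    fill_voids,
    flow_accumulation,
    flow_direction,
    linear_chain_scene,
    cone_island_scene,
    confluence_scene,
    random_terrain_scene,
)

NODATA = -9999.0


def make_grid(values, cell_size=90.0, nodata=NODATA, origin_x=0.0, origin_y=None):
    values = np.asarray(values, dtype=float)
    if origin_y is None:
        origin_y = values.shape[0] * cell_size
    return RasterGrid(
        values=values,
        origin_x=origin_x,
        origin_y=origin_y,
        cell_size=cell_size,
        nodata=nodata,
    )


def route(grid):
    """Condition a grid and return (conditioned, directions, accumulation)."""
    part = classify_nodata(grid)
    cond = fill_depressions(fill_voids(grid, part), ocean=part)
    dirs = flow_direction(cond, ocean=classify_nodata(cond))
    return cond, dirs, flow_accumulation(dirs)


def random_island(nrows, ncols, seed, margin=2):
    """Raw (unconditioned) seeded terrain with an ocean margin."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(1.0, 100.0, size=(nrows, ncols))
    values[:margin, :] = NODATA
    values[-margin:, :] = NODATA
    values[:, :margin] = NODATA
    values[:, -margin:] = NODATA
    return make_grid(values)


@pytest.fixture
def ramp_1x5():
    """East-descending single-row river flanked by ocean."""
    vals = np.full((3, 5), NODATA)
    vals[1] = [5, 4, 3, 2, 1]
    return make_grid(vals)


@pytest.fixture(scope="session")
def chain_scene():
    return linear_chain_scene(10, cells_per_village=3)


@pytest.fixture(scope="session")
def cone_scene():
    return cone_island_scene(20, 8)


@pytest.fixture(scope="session")
def confluence():
    return confluence_scene(5)


@pytest.fixture(scope="session")
def random_scene():
    return random_terrain_scene(60, 60, seed=42, n_regions=12)
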