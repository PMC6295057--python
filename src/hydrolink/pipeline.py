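"""End-to-end pipeline: DEM tiles to the final upstream-region table.

Stages, in order: mosaic -> void fill -> depression filling -> D8 directions
-> accumulation -> region rasterization -> pour points -> per-region
delineation -> table + run report. Per-region work is embarrassingly
parallel and memory-resident; only the final table and report are written.
The assembled output is byte-identical for any worker count and across
repeated runs on the same inputs.

Configuration is a flat ``key = value`` text file (``#`` comments allowed);
see :data:`REQUIRED_KEYS` and :data:`DEFAULTS`. Programmatic callers can
pass a plain dict instead.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .condition import fill_depressions
from .errors import ConfigError, HydrolinkError
from .grid import RasterGrid, read_grid, mosaic, aggregate, write_grid
from .regions import read_regions, rasterize, place_pour_points
from .routing import (
    accumulation_grid_to_raster,
    direction_grid_to_raster,
    flow_accumulation,
    flow_direction,
)
from .table import RunReport, UpstreamTable, build_table, write_table
from .voids import classify_nodata, fill_voids

logger = logging.getLogger(__name__)

REQUIRED_KEYS = ("dem", "regions", "id_field", "out_table")
DEFAULTS = {
    "epsilon": "0.001",
    "workers": "1",
    "aggregate_factor": "1",
    "out_report": "",
    "ocean_mask": "",
    "intermediates_dir": "",
}


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` configuration file."""
    config: dict[str, str] = {}
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    return config


def _validated(config: dict[str, str]) -> dict[str, str]:
    merged = {**DEFAULTS, **config}
    missing = [k for k in REQUIRED_KEYS if not merged.get(k)]
    if missing:
        raise ConfigError(f"config is missing required keys: {missing}")
    try:
        if float(merged["epsilon"]) <= 0:
            raise ConfigError("epsilon must be > 0")
        if int(merged["workers"]) < 1:
            raise ConfigError("workers must be >= 1")
        if int(merged["aggregate_factor"]) < 1:
            raise ConfigError("aggregate_factor must be >= 1")
    except ValueError as exc:
        raise ConfigError(f"non-numeric pipeline parameter: {exc}") from exc
    unknown = set(merged) - set(REQUIRED_KEYS) - set(DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return merged


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, HydrolinkError):
                exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",)
            return False

    return _Ctx()


def run_pipeline(config: dict[str, str] | str | Path) -> tuple[Path, RunReport]:
    """Execute the full chain; returns (table path, run report).

    ``config`` is a dict or the path of a key-value file. All validation
    happens before any raster is read. Partial outputs are removed on error.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    cfg = _validated(config)

    with _stage("mosaic"):
        tile_paths = [p for p in cfg["dem"].split(",") if p.strip()]
        tiles = [read_grid(p.strip()) for p in tile_paths]
        grid = tiles[0] if len(tiles) == 1 else mosaic(tiles)
    if int(cfg["aggregate_factor"]) > 1:
        with _stage("aggregate"):
            grid = aggregate(grid, int(cfg["aggregate_factor"]))
    with _stage("void_fill"):
        override = None
        if cfg["ocean_mask"]:
            override = read_grid(cfg["ocean_mask"]).values > 0
        partition = classify_nodata(grid, ocean_override=override)
        filled = fill_voids(grid, partition)
        logger.info(
            "voids filled: %d cells; ocean: %d cells",
            int(partition.void_mask.sum()),
            int(partition.ocean_mask.sum()),
        )
    with _stage("condition"):
        conditioned = fill_depressions(
            filled, epsilon=float(cfg["epsilon"]), ocean=classify_nodata(filled)
        )
    with _stage("flow_direction"):
        dirs = flow_direction(conditioned, ocean=classify_nodata(conditioned))
    with _stage("flow_accumulation"):
        acc = flow_accumulation(dirs)
    with _stage("regions"):
        regions = read_regions(cfg["regions"], cfg["id_field"])
        labels = rasterize(regions, grid)
        logger.info(
            "regions read: %d; without cells: %d", len(regions), len(labels.skipped)
        )
    with _stage("pour_points"):
        pour_points = place_pour_points(labels, acc)
    report = RunReport()
    for rid in labels.skipped:
        report.skipped.append((rid, "no labelled cells"))
    placed = {p.region_id for p in pour_points}
    for rid in regions.ids():
        if rid not in placed and rid not in labels.skipped:
            report.skipped.append((rid, "no labelled land cell carries flow"))
    with _stage("delineation"):
        table = build_table(
            dirs, labels, pour_points, workers=int(cfg["workers"]), report=report
        )

    if cfg["intermediates_dir"]:
        inter = Path(cfg["intermediates_dir"])
        inter.mkdir(parents=True, exist_ok=True)
        write_grid(conditioned, inter / "conditioned.asc")
        write_grid(direction_grid_to_raster(dirs), inter / "directions.asc")
        write_grid(accumulation_grid_to_raster(acc), inter / "accumulation.asc")

    out_table = Path(cfg["out_table"])
    try:
        write_table(table, out_table)
    except Exception:
        out_table.unlink(missing_ok=True)  # never leave a partial table behind
        raise
    if cfg["out_report"]:
        report.write(cfg["out_report"])
    logger.info(
        "regions read=%d delineated=%d skipped=%d failed=%d relations=%d",
        len(regions),
        len(report.delineated),
        len(report.skipped),
        len(report.failed),
        table.total_relations(),
    )
    return out_table, report
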