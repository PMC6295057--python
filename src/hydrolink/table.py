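"""The one-to-many upstream-region table: extraction, assembly, CSV dialect.

For each focal region, the table lists every *other* region with at least
one labelled cell inside the focal region's watershed ("wholly or partially
contained" — one cell suffices). A region never lists itself, so the
realized relation count for an n-region single-river chain is n(n-1)/2
(the theory module also exposes the self-inclusive convention used for the
headline theoretical bounds).

CSV dialect: one record per focal region — the focal id first, then its
upstream ids, comma-delimited, newline-terminated, records sorted by focal
id. Shards produced by parallel runs merge by concatenation + sort; the same
focal id in two shards is a merge error.

Per-region delineation tasks are independent; ``build_table`` runs them
serially or on a process pool, and the assembled table is identical for any
worker count. A task that fails is retried once and then recorded as failed
in the run report — never silently dropped.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from .errors import MergeError, ParameterError, TableFormatError
from .regions import BACKGROUND, PourPoint, RegionLabelGrid
from .routing import FlowDirectionGrid
from .watershed import WatershedMask, delineate

logger = logging.getLogger(__name__)


@dataclass
class UpstreamTable:
    """Mapping focal region id -> sorted list of upstream region ids."""

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        for rid, ups in self.entries.items():
            if rid in ups:
                raise TableFormatError(f"region {rid!r} lists itself as upstream")
            self.entries[rid] = sorted(ups)

    def count(self, region_id: str) -> int:
        return len(self.entries[region_id])

    def total_relations(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, UpstreamTable) and self.entries == other.entries


@dataclass
class RunReport:
    """Per-region outcome bookkeeping so that totals reconcile:
    regions read = delineated + skipped + failed."""

    delineated: list[str] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    failed: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("region_id,status,reason\n")
            for rid in self.delineated:
                fh.write(f"{rid},ok,\n")
            for rid, reason in self.skipped:
                fh.write(f"{rid},skipped,{reason}\n")
            for rid, reason in self.failed:
                fh.write(f"{rid},failed,{reason}\n")
        return path


def extract_upstream(
    labels: RegionLabelGrid, mask: WatershedMask, self_id: str
) -> list[str]:
    """All regions (other than ``self_id``) with >= 1 labelled cell in the mask."""
    found: set[int] = set()
    lab = labels.labels
    for r, c in mask.cells:
        idx = lab[r, c]
        if idx != BACKGROUND:
            found.add(int(idx))
    ids = {labels.region_ids[i] for i in found}
    ids.discard(self_id)
    return sorted(ids)


# -- parallel task plumbing -------------------------------------------------

_WORKER_DIRS: FlowDirectionGrid | None = None
_WORKER_LABELS: RegionLabelGrid | None = None


def _worker_init(dirs: FlowDirectionGrid, labels: RegionLabelGrid) -> None:
    global _WORKER_DIRS, _WORKER_LABELS
    _WORKER_DIRS = dirs
    _WORKER_LABELS = labels


def _worker_task(pour: PourPoint) -> tuple[str, list[str]]:
    assert _WORKER_DIRS is not None and _WORKER_LABELS is not None
    mask = delineate(_WORKER_DIRS, pour)
    return pour.region_id, extract_upstream(_WORKER_LABELS, mask, pour.region_id)


def _run_one(
    dirs: FlowDirectionGrid, labels: RegionLabelGrid, pour: PourPoint
) -> tuple[str, list[str]]:
    mask = delineate(dirs, pour)
    return pour.region_id, extract_upstream(labels, mask, pour.region_id)


def build_table(
    dirs: FlowDirectionGrid,
    labels: RegionLabelGrid,
    pour_points: list[PourPoint],
    workers: int = 1,
    report: RunReport | None = None,
) -> UpstreamTable:
    """Delineate every pour point and assemble the upstream table.

    The result is independent of ``workers`` and of task completion order:
    entries are keyed by region id and each region's task is a pure function
    of the shared direction and label grids.
    """
    if workers < 1:
        raise ParameterError(f"workers must be >= 1, got {workers}")
    if report is None:
        report = RunReport()
    tasks = sorted(pour_points, key=lambda p: p.region_id)
    entries: dict[str, list[str]] = {}

    if workers == 1 or len(tasks) <= 1:
        outcomes = []
        for pour in tasks:
            try:
                outcomes.append(_run_one(dirs, labels, pour))
            except Exception:
                try:  # one retry, matching the parallel path's contract
                    outcomes.append(_run_one(dirs, labels, pour))
                except Exception as exc:
                    outcomes.append((pour.region_id, exc))
    else:
        outcomes = []
        with ProcessPoolExecutor(
            max_workers=workers, initializer=_worker_init, initargs=(dirs, labels)
        ) as pool:
            futures = {p.region_id: pool.submit(_worker_task, p) for p in tasks}
            for pour in tasks:
                fut = futures[pour.region_id]
                try:
                    outcomes.append(fut.result())
                except Exception:
                    # retry once, in-process, before declaring the region failed
                    try:
                        outcomes.append(_run_one(dirs, labels, pour))
                    except Exception as exc:
                        outcomes.append((pour.region_id, exc))

    for rid, result in outcomes:
        if isinstance(result, Exception):
            logger.warning("region %s failed: %s", rid, result)
            report.failed.append((rid, str(result)))
        else:
            logger.debug("region %s: %d upstream", rid, len(result))
            entries[rid] = result
            report.delineated.append(rid)
    return UpstreamTable(entries=entries)


# -- CSV dialect ------------------------------------------------------------


def write_table(table: UpstreamTable, path: str | Path) -> Path:
    """Write the one-to-many CSV: focal id, then upstream ids, per line."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rid in sorted(table.entries):
            fh.write(",".join([rid, *table.entries[rid]]))
            fh.write("\n")
    return path


def read_table(path: str | Path) -> UpstreamTable:
    path = Path(path)
    entries: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(",")
            if not fields[0]:
                raise TableFormatError(f"{path}:{lineno}: empty focal region id")
            if fields[0] in entries:
                raise TableFormatError(
                    f"{path}:{lineno}: focal id {fields[0]!r} repeated"
                )
            ups = [f for f in fields[1:] if f]
            if len(ups) != len(fields) - 1:
                raise TableFormatError(
                    f"{path}:{lineno}: empty upstream id field"
                )
            entries[fields[0]] = ups
    return UpstreamTable(entries=entries)


def merge_shards(shard_paths: list[str | Path], out_path: str | Path) -> Path:
    """Concatenate shard CSVs into the final sorted table.

    The same focal id appearing in two shards is a :class:`MergeError` —
    shards partition the regions, so a duplicate means a bookkeeping bug.
    """
    merged: dict[str, list[str]] = {}
    origin: dict[str, str] = {}
    for sp in shard_paths:
        shard = read_table(sp)
        for rid, ups in shard.entries.items():
            if rid in merged:
                raise MergeError(
                    f"focal id {rid!r} appears in both {origin[rid]} and {sp}"
                )
            merged[rid] = ups
            origin[rid] = str(sp)
    return write_table(UpstreamTable(entries=merged), out_path)
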