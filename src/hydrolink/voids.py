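"""Separate ocean nodata from interior data voids and interpolate the voids.

Radar elevation products carry two very different kinds of missing data: the
sea surrounding an island (which must stay missing — it is the drainage
target) and isolated interior holes left by the sensor (which must be filled
before any flow can be routed across them). The split is purely topological:
nodata that is 4-connected to the grid border is ocean, the rest is void.

Voids are filled by harmonic (Laplace) interpolation from their valid rim:
each void cell converges to the average of its four cardinal neighbors.
This reproduces affine surfaces across holes exactly — the property that
matters for drainage directions — and obeys the maximum principle, so filled
values can never overshoot the rim values (they are clamped to the rim's
range anyway as a belt-and-braces guarantee).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import VoidError
from .grid import RasterGrid

#: 4-connectivity structuring element for ocean/void classification.
_CROSS = ndimage.generate_binary_structure(2, 1)

#: Refuse to invent terrain inside holes larger than this many cells.
MAX_VOID_CELLS = 10_000

#: Convergence threshold for the harmonic fill, meters.
FILL_TOLERANCE = 1e-6


@dataclass(frozen=True)
class NodataPartition:
    """The nodata cells of a grid split into ocean and interior voids.

    ``ocean_mask`` holds nodata 4-connected to the border; ``void_mask`` holds
    the rest. The two are disjoint and together cover the nodata set exactly.
    """

    ocean_mask: np.ndarray
    void_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.ocean_mask.shape != self.void_mask.shape:
            raise VoidError("ocean and void masks must share a shape")
        if np.any(self.ocean_mask & self.void_mask):
            raise VoidError("a cell cannot be both ocean and void")


def classify_nodata(
    grid: RasterGrid, ocean_override: np.ndarray | None = None
) -> NodataPartition:
    """Flood-fill nodata from the border (4-connectivity) to find the ocean.

    ``ocean_override`` — an optional boolean mask — replaces the
    border-connectivity rule entirely: nodata cells under the mask are ocean,
    all other nodata cells are voids.
    """
    nodata = ~grid.valid_mask()
    if ocean_override is not None:
        override = np.asarray(ocean_override, dtype=bool)
        if override.shape != nodata.shape:
            raise VoidError("ocean override mask shape does not match the grid")
        ocean = nodata & override
        return NodataPartition(ocean_mask=ocean, void_mask=nodata & ~ocean)
    if not nodata.any():
        return NodataPartition(ocean_mask=nodata.copy(), void_mask=nodata.copy())
    labels, _ = ndimage.label(nodata, structure=_CROSS)
    border_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border_labels = border_labels[border_labels != 0]
    ocean = np.isin(labels, border_labels)
    return NodataPartition(ocean_mask=ocean, void_mask=nodata & ~ocean)


def fill_voids(
    grid: RasterGrid,
    partition: NodataPartition | None = None,
    max_void_cells: int = MAX_VOID_CELLS,
    tol: float = FILL_TOLERANCE,
) -> RasterGrid:
    """Interpolate interior voids; leave ocean nodata and valid cells untouched.

    Solves the discrete Laplace equation over the void cells with the
    surrounding valid cells as Dirichlet boundary (Jacobi iteration to
    ``tol``), then clamps each void component to the value range of its valid
    rim. Idempotent: a grid with no voids is returned as a copy.
    """
    if partition is None:
        partition = classify_nodata(grid)
    void = partition.void_mask
    out = grid.values.copy()
    if not void.any():
        return grid.copy_with(out)

    labels, ncomp = ndimage.label(void, structure=_CROSS)
    sizes = ndimage.sum_labels(void, labels, index=np.arange(1, ncomp + 1))
    if sizes.max(initial=0) > max_void_cells:
        raise VoidError(
            f"void of {int(sizes.max())} cells exceeds the {max_void_cells}-cell "
            "limit; refusing to interpolate terrain at that scale"
        )

    valid = grid.valid_mask()
    # Dirichlet data: valid cells keep their value; ocean contributes nothing.
    # A void component's rim is all valid by construction (any nodata neighbor
    # would belong to the same 4-connected component).
    work = np.where(valid, out, 0.0)
    # seed void cells at the mean of their component's rim for faster convergence
    rim = ndimage.binary_dilation(void, structure=_CROSS) & valid
    comp_bounds: list[tuple[float, float]] = []
    for comp in range(1, ncomp + 1):
        comp_mask = labels == comp
        comp_rim = ndimage.binary_dilation(comp_mask, structure=_CROSS) & valid
        if not comp_rim.any():
            raise VoidError(
                f"void component {comp} has no valid neighbor; classification "
                "invariant violated"
            )
        rim_vals = grid.values[comp_rim]
        comp_bounds.append((float(rim_vals.min()), float(rim_vals.max())))
        work[comp_mask] = float(rim_vals.mean())
    del rim

    vr, vc = np.nonzero(void)
    up, down = (vr - 1, vc), (vr + 1, vc)
    left, right = (vr, vc - 1), (vr, vc + 1)
    max_iter = 100 * max(grid.nrows, grid.ncols)
    for _ in range(max_iter):
        new = 0.25 * (work[up] + work[down] + work[left] + work[right])
        delta = np.abs(new - work[vr, vc]).max()
        work[vr, vc] = new
        if delta < tol:
            break

    for comp, (lo, hi) in enumerate(comp_bounds, start=1):
        comp_mask = labels == comp
        out[comp_mask] = np.clip(work[comp_mask], lo, hi)
    return grid.copy_with(out)
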