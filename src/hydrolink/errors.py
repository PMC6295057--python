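"""Exception hierarchy.

Every stage raises a subclass of :class:`HydrolinkError` so the pipeline
driver can attach the stage name and offending input before re-raising.
"""


class HydrolinkError(Exception):
    """Base class for all errors raised by this package."""


class GridFormatError(HydrolinkError):
    """A raster file could not be parsed (names the byte/line where parsing failed)."""


class UnsupportedInputError(HydrolinkError):
    """Input is syntactically valid but outside the supported subset (e.g. multiband)."""


class GridInvariantError(HydrolinkError):
    """A RasterGrid violates its own invariants (non-positive cell size, ragged rows...)."""


class AlignmentError(HydrolinkError):
    """Mosaic tiles whose origins are not offset by integer multiples of the cell size."""


class MosaicConflictError(HydrolinkError):
    """Overlapping mosaic tiles disagree on a valid value; message names the first cell."""


class ParameterError(HydrolinkError):
    """A numeric parameter is out of its documented range."""


class EmptyInputError(HydrolinkError):
    """An operation received an input with no usable content (e.g. all-nodata grid)."""


class VoidError(HydrolinkError):
    """Interior-void handling failed (void too large, or no valid boundary)."""


class UnconditionedInputError(HydrolinkError):
    """Flow routing found a cell with no descending neighbor and no outlet adjacency."""


class CorruptedDirectionError(HydrolinkError):
    """The D8 pointer grid contains a cycle or an out-of-grid pointer."""


class InvalidPourError(HydrolinkError):
    """A pour point lies on a nodata cell."""


class DuplicateIdError(HydrolinkError):
    """Two region records share an id but carry different geometries."""


class TableFormatError(HydrolinkError):
    """An upstream-table CSV line failed to parse; message carries the line number."""


class MergeError(HydrolinkError):
    """Shard merging found the same focal region id in more than one shard."""


class ConfigError(HydrolinkError):
    """The pipeline configuration is missing a required key or names a bad value."""
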