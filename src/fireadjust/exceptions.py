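"""Exception hierarchy for grid, format, and fitting errors."""


class FireAdjustError(Exception):
    """Base class for all package errors."""


class GridError(FireAdjustError):
    """Grids are misaligned, off-lattice, or otherwise incompatible."""


class FormatError(FireAdjustError):
    """A file or table violates the expected layout (e.g. non-monthly time axis)."""


class AlignmentError(FireAdjustError):
    """Year labels of two annual series cannot be aligned."""


class InsufficientDataError(FireAdjustError):
    """Too few years (or months) to carry out an estimate."""


class UndefinedFitError(FireAdjustError):
    """A regression is undefined (e.g. zero-variance regressor)."""
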