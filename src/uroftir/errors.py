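"""Exception hierarchy for the uroftir pipeline.

Every stage raises a subclass of :class:`UroftirError` so the pipeline
driver can abort with the stage name and the offending sample id.
"""


class UroftirError(Exception):
    """Base class for all package errors."""


class ParseError(UroftirError):
    """A spectrum file could not be parsed (carries the line number)."""


class FormatError(UroftirError):
    """A spectrum file is structurally invalid (e.g. too few points)."""


class GridError(UroftirError):
    """Wavenumber grids are non-uniform, mismatched, or out of range."""


class IdentityError(UroftirError):
    """Spectra from different patients were mixed where one was expected."""


class MissingDataError(UroftirError):
    """A patient listed in the metadata has no spectra."""


class LabelError(UroftirError):
    """A label outside {0, 1} was encountered."""


class ParameterError(UroftirError, ValueError):
    """An operation was configured with invalid parameters."""


class SizeError(UroftirError):
    """An input vector or matrix has an incompatible size."""


class ShapeError(UroftirError):
    """Matrix column count does not match the fitted model."""


class DegenerateSpectrumError(UroftirError):
    """A spectrum has zero variance and cannot be normalised."""


class UndefinedMetricError(UroftirError):
    """A metric is undefined for the given input (e.g. single-class labels)."""


class StratificationError(UroftirError):
    """A class is too small for the requested stratified operation."""


class WeightingError(UroftirError):
    """Class weights are undefined (single class present)."""


class DataError(UroftirError):
    """Empty or inconsistent training data."""


class FoldError(UroftirError):
    """Cross-validation fold count exceeds the minority-class size."""


class FractionError(UroftirError):
    """A learning-curve fraction is too small for stratification."""


class LookupError_(UroftirError):
    """A requested wavenumber is not on the grid."""
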