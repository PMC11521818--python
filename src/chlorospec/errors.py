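"""Exception hierarchy shared across the package."""


class ChlorospecError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChlorospecError):
    """Invalid configuration values (bounds, counts, thresholds)."""


class DomainError(ChlorospecError):
    """Physically meaningless input (negative pigment, non-positive volume)."""


class RangeError(ChlorospecError):
    """Requested wavelength outside the spectral grid."""


class UndefinedIndexError(ChlorospecError):
    """A spectral index hit a zero denominator; carries the index name."""

    def __init__(self, index_name: str, message: str | None = None):
        self.index_name = index_name
        super().__init__(message or f"index {index_name!r} is undefined for this spectrum")


class CatalogError(ChlorospecError):
    """Unknown index name."""


class GroupingError(ChlorospecError):
    """A chlorophyll group is empty or too small to profile."""


class SelectionError(ChlorospecError):
    """Fewer loading extrema than requested wavelengths."""


class DecompositionError(ChlorospecError):
    """Rank-deficient or degenerate matrix input."""


class InputError(ChlorospecError):
    """Malformed array input (length/dimension mismatch, non-finite values)."""


class SplitError(ChlorospecError):
    """Dataset too small for the requested train/validation split."""


class FitError(ChlorospecError):
    """A model or calibration could not be fitted (e.g. zero variance)."""


class ZeroVarianceError(ChlorospecError):
    """R-squared undefined because the reference values have no variance.

    Carries the metrics that remain well defined in ``partial``.
    """

    def __init__(self, message: str, partial=None):
        self.partial = partial
        super().__init__(message)


class ConditioningError(ChlorospecError):
    """Kernel matrix not positive definite after jitter escalation."""
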