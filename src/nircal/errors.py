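"""Exception hierarchy for nircal.

All errors derive from :class:`NircalError` (a ``ValueError``) so callers can
catch the package's failures with a single except clause while still getting
standard-library semantics.
"""


class NircalError(ValueError):
    """Base class for all nircal errors."""


class InvalidDesignError(NircalError):
    """A generator or experiment design parameter is out of its valid range."""


class InsufficientReplicatesError(NircalError):
    """An operation requiring replicate acquisitions received fewer than two."""


class NonPositiveSignalError(NircalError):
    """Transflectance contains values <= 0, so log10(1/x) is undefined."""


class DivisionDegenerateError(NircalError):
    """A coefficient of variation denominator (replicate mean) is zero."""


class EmptySpectrumError(NircalError):
    """A filter removed every wavelength channel."""


class DegenerateSpectrumError(NircalError):
    """A spectrum row has zero variance and cannot be standardized."""


class UncorrectableSpectrumError(NircalError):
    """MSC slope is numerically zero; the affine correction cannot be inverted."""


class InvalidParametersError(NircalError):
    """Savitzky-Golay window/degree/derivative parameters are inconsistent."""


class DegenerateSplitError(NircalError):
    """A class split left one class empty."""


class EmptySelectionError(NircalError):
    """No wavelength passed the significance screen."""


class CollinearDesignError(NircalError):
    """The regression design matrix is rank deficient."""


class ModelMismatchError(NircalError):
    """A model term's wavelength is absent from the spectra it must score."""


class InvalidFractionError(NircalError):
    """A holdout fraction lies outside (0, 1) or leaves a partition too small."""


class FoldFitError(NircalError):
    """A cross-validation fold failed to fit."""


class FormatError(NircalError):
    """A dataset or report file does not conform to the expected dialect."""
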