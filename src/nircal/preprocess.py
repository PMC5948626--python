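"""Spectral pretreatment operators.

Transflectance -> absorbance conversion, the coefficient-of-variation (CV)
noisy-band filter, and the three scatter/baseline corrections commonly
compared in NIR calibration work: standard normal variate (SNV),
multiplicative scatter correction (MSC) and Savitzky-Golay (SG)
smoothing/derivative filtering.

All operators act on an :class:`AbsorbanceMatrix` (samples x channels) and
record themselves in its provenance chain, except the CV filter, which is
computed on raw transflectance replicates: the CV denominator is the
replicate mean, which is near zero in absorbance units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_coeffs

from .datasets import SpectraDataset
from .errors import (
    DegenerateSpectrumError,
    DivisionDegenerateError,
    EmptySpectrumError,
    InsufficientReplicatesError,
    InvalidParametersError,
    NonPositiveSignalError,
    UncorrectableSpectrumError,
)

__all__ = [
    "AbsorbanceMatrix",
    "BandFilterResult",
    "to_absorbance",
    "cv_per_wavelength",
    "remove_noisy_bands",
    "snv",
    "msc",
    "msc_coefficients",
    "savitzky_golay",
    "sg_coefficients",
]


@dataclass
class AbsorbanceMatrix:
    """Absorbance spectra (samples x channels) with their wavelength grid and
    the chain of preprocessing steps that produced them."""

    values: np.ndarray
    wavelengths: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParametersError("absorbance must be (samples, channels)")
        if self.values.shape[1] != self.wavelengths.size:
            raise InvalidParametersError("channel axis must match the wavelength grid")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def _derive(self, values, wavelengths, step: str) -> "AbsorbanceMatrix":
        return AbsorbanceMatrix(values, wavelengths, self.provenance + (step,))


@dataclass
class BandFilterResult:
    """Per-channel CV (percent), the mean-CV threshold, and the retained mask."""

    cv: np.ndarray
    threshold: float
    retained_mask: np.ndarray

    @property
    def retained_indices(self) -> np.ndarray:
        return np.nonzero(self.retained_mask)[0]

    @property
    def removed_indices(self) -> np.ndarray:
        return np.nonzero(~self.retained_mask)[0]

    def apply(self, spectra: AbsorbanceMatrix) -> AbsorbanceMatrix:
        """Restrict an absorbance matrix to the retained channels."""
        if spectra.n_channels != self.retained_mask.size:
            raise InvalidParametersError(
                "band filter and spectra have different channel counts"
            )
        return spectra._derive(
            spectra.values[:, self.retained_mask],
            spectra.wavelengths[self.retained_mask],
            "cv_band_filter",
        )


def to_absorbance(transflectance: np.ndarray, wavelengths: np.ndarray) -> AbsorbanceMatrix:
    """Elementwise ``log10(1/x)`` of strictly positive transflectance.

    Raw detector units give negative absorbance; downstream operators are
    offset-invariant so only relative structure matters.
    """
    t = np.asarray(transflectance, dtype=float)
    bad = np.argwhere(t <= 0)
    if bad.size:
        raise NonPositiveSignalError(
            f"transflectance must be strictly positive; offending indices "
            f"(first 5): {bad[:5].tolist()}"
        )
    return AbsorbanceMatrix(-np.log10(t), wavelengths, ("absorbance",))


def cv_per_wavelength(dataset: SpectraDataset, method: str = "mean") -> np.ndarray:
    """Per-channel coefficient of variation, in percent.

    CV = 100 * s / mean is computed across acquisitions for each (sample,
    channel); per channel the default aggregation is the unweighted mean over
    samples (``method="mean"``).  ``method="pooled"`` instead pools replicate
    variances across samples before forming one CV per channel.
    """
    if dataset.n_acquisitions < 2:
        raise InsufficientReplicatesError("CV requires at least two acquisitions")
    t = dataset.transflectance
    mean = t.mean(axis=1)
    if np.any(mean == 0):
        i, v = np.argwhere(mean == 0)[0]
        raise DivisionDegenerateError(
            f"zero replicate mean at sample {i}, channel {v}"
        )
    sd = t.std(axis=1, ddof=1)
    if method == "mean":
        return (100.0 * sd / mean).mean(axis=0)
    if method == "pooled":
        pooled_sd = np.sqrt((sd**2).mean(axis=0))
        return 100.0 * pooled_sd / mean.mean(axis=0)
    raise InvalidParametersError(f"unknown CV aggregation method: {method!r}")


def remove_noisy_bands(cv: np.ndarray) -> BandFilterResult:
    """Flag channels whose CV exceeds the mean CV across all channels."""
    cv = np.asarray(cv, dtype=float)
    if not np.all(np.isfinite(cv)):
        raise InvalidParametersError("CV vector must be finite")
    threshold = float(cv.mean())
    retained = cv <= threshold
    if not retained.any():
        raise EmptySpectrumError("CV filter removed every channel")
    return BandFilterResult(cv=cv, threshold=threshold, retained_mask=retained)


def snv(spectra: AbsorbanceMatrix) -> AbsorbanceMatrix:
    """Standard normal variate: per-spectrum standardization (ddof=1)."""
    x = spectra.values
    if x.shape[1] < 2:
        raise DegenerateSpectrumError("SNV needs at least two channels per spectrum")
    sd = x.std(axis=1, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        raise DegenerateSpectrumError(
            f"zero-variance spectrum rows cannot be standardized: {zero.tolist()}"
        )
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return spectra._derive(out, spectra.wavelengths, "snv")


def msc_coefficients(
    spectra: AbsorbanceMatrix, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row OLS fit ``x_i = a_i + b_i * reference``.

    Returns (a, b, reference); the reference defaults to the column-wise mean
    spectrum of the input.
    """
    x = spectra.values
    if reference is None:
        if x.shape[0] < 2:
            raise DegenerateSpectrumError(
                "MSC needs at least two spectra to form a mean reference"
            )
        reference = x.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (x.shape[1],):
        raise InvalidParametersError("MSC reference must match the channel axis")
    ref_c = reference - reference.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise UncorrectableSpectrumError("constant MSC reference")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = x.mean(axis=1) - b * reference.mean()
    small = np.nonzero(np.abs(b) < 1e-12)[0]
    if small.size:
        raise UncorrectableSpectrumError(
            f"MSC slope numerically zero for rows {small.tolist()}"
        )
    return a, b, reference


def msc(
    spectra: AbsorbanceMatrix, reference: np.ndarray | None = None
) -> AbsorbanceMatrix:
    """Multiplicative scatter correction: invert the per-row affine fit to the
    reference spectrum, ``(x_i - a_i) / b_i``."""
    a, b, _ = msc_coefficients(spectra, reference)
    out = (spectra.values - a[:, None]) / b[:, None]
    return spectra._derive(out, spectra.wavelengths, "msc")


def sg_coefficients(window: int, degree: int, derivative: int = 0) -> np.ndarray:
    """Savitzky-Golay convolution coefficients (applied by dot product with
    the window in increasing-wavelength order, in channel units)."""
    if window % 2 == 0 or window < 3:
        raise InvalidParametersError("SG window must be odd and >= 3")
    if not 0 <= derivative <= degree < window:
        raise InvalidParametersError(
            "SG requires window > degree >= derivative >= 0"
        )
    return savgol_coeffs(window, degree, deriv=derivative, delta=1.0, use="dot")


def savitzky_golay(
    spectra: AbsorbanceMatrix, window: int, degree: int, derivative: int = 0
) -> AbsorbanceMatrix:
    """Savitzky-Golay filtering with edge channels dropped.

    Only channels with a full window are kept, so the wavelength grid is
    shortened by (window - 1)/2 per side.  Derivatives are per channel index
    (the default grid is uniform in nm).
    """
    coeffs = sg_coefficients(window, degree, derivative)
    if spectra.n_channels < window:
        raise InvalidParametersError("fewer channels than the SG window")
    half = window // 2
    out = sliding_window_view(spectra.values, window, axis=1) @ coeffs
    wl = spectra.wavelengths[half:-half]
    return spectra._derive(out, wl, f"sg(window={window},degree={degree},deriv={derivative})")
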