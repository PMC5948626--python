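"""Synthetic transflectance spectra with the statistical structure of an
olive-oil NIR calibration study.

The generator emulates a transflectance FT-NIR acquisition of olive-oil
samples whose total polyphenol content is the calibration target:

* a base series of oils evenly spanning a concentration range, pairwise
  blended to enlarge the sample set;
* repeated acquisitions per sample under a lamp regulated so the raw
  detector reading ("ut", units of transflectance) at a reference
  wavelength hits a power target;
* polyphenol-linked absorption shoulders whose maximal spectral slope sits
  at configurable center wavelengths, riding on a broad lamp/transmission
  background that peaks at the reference wavelength;
* per-acquisition multiplicative/additive scatter disturbances (the class
  of artefact SNV and MSC are designed to remove) and additive channel
  noise that is larger inside a designated low-SNR band.

The energy balance per wavelength is ``P_r = P_t - P_abs - L``: received
power equals transmitted lamp power minus sample absorption minus hardware
losses.  With Beer-law absorbance A this gives
``P_r = gain * S(lambda) * (10**(-A) - loss_fraction)``, clamped at a small
positive floor so absorbance stays defined.

Total polyphenols are modelled as three latent compound groups, one per
planted band, whose per-sample proportions jitter around fixed fractions.
This keeps the three bands from being exactly collinear in the total, so a
three-term linear model is identifiable; setting ``band_weight_sd = 0``
makes every band center exactly affine in total concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtr

from .errors import InsufficientReplicatesError, InvalidDesignError

__all__ = [
    "GeneratorConfig",
    "SpectraDataset",
    "GroundTruth",
    "make_base_concentrations",
    "blend_consecutive",
    "generate_dataset",
    "replicate_statistics",
]

#: floor applied to transflectance so log10(1/x) stays defined (ut)
TRANSFLECTANCE_FLOOR = 1e-6


def _default_grid() -> np.ndarray:
    return np.linspace(900.0, 2600.0, 921)


@dataclass(frozen=True)
class GeneratorConfig:
    """Design parameters of the synthetic study.

    Defaults reproduce the reference study design: 11 base oils evenly
    spanning 1017-2169 mg/kg blended to 21 samples, 10 acquisitions each,
    921 channels over 900-2600 nm, lamp regulated to 400 ut at 1600 nm,
    polyphenol features at 1830/1917/2189 nm and a low-SNR band at
    2240-2600 nm with 10x the clean channel noise.
    """

    n_base_samples: int = 11
    conc_min: float = 1017.0
    conc_max: float = 2169.0
    blend: bool = True
    wavelengths: np.ndarray = field(default_factory=_default_grid)
    n_acquisitions: int = 10
    power_target: float = 400.0
    reference_wavelength: float = 1600.0
    informative_band_centers: tuple[float, ...] = (1830.0, 1917.0, 2189.0)
    informative_band_widths: float = 15.0
    #: absorbance per (mg/kg) at full shoulder height
    informative_band_strengths: float = 3e-5
    #: latent compound-group fractions of total polyphenols, one per band
    band_fractions: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    #: per-sample composition jitter; 0 makes bands exactly collinear in total
    band_weight_sd: float = 0.20
    #: Gaussian width (nm) of the lamp/transmission background peaking at the
    #: reference wavelength; ignored if background_shape is given
    background_width: float = 600.0
    background_shape: np.ndarray | None = None
    noisy_band: tuple[float, float] = (2240.0, 2600.0)
    noise_sd_clean: float = 2.5
    noise_sd_noisy: float = 25.0
    scatter_slope_sd: float = 0.02
    scatter_offset_sd: float = 0.002
    loss_fraction: float = 0.05
    #: SD (mg/kg) of the reference-method (chemical assay) error added to the
    #: reported concentrations; the spectra reflect the true values.  Sized to
    #: the error floor a wet-chemistry polyphenol assay leaves in calibration.
    reference_noise_sd: float = 80.0
    #: channel-axis Gaussian correlation length of the additive noise
    #: (channels); the default models smooth baseline wobble / drift, the
    #: dominant disturbance of a stabilized FT-NIR; 0 gives white detector
    #: noise
    noise_correlation_length: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise InvalidDesignError("wavelength grid must be strictly increasing")
        if wl[0] < 900.0 - 1e-9 or wl[-1] > 2600.0 + 1e-9:
            raise InvalidDesignError("wavelength grid must lie within [900, 2600] nm")
        if self.n_base_samples < 2:
            raise InvalidDesignError("need at least two base samples")
        if self.conc_min >= self.conc_max:
            raise InvalidDesignError("conc_min must be below conc_max")
        if self.n_acquisitions < 1:
            raise InvalidDesignError("n_acquisitions must be positive")
        centers = np.asarray(self.informative_band_centers, dtype=float)
        if np.any(centers < wl[0]) or np.any(centers > wl[-1]):
            raise InvalidDesignError("informative band center outside the grid span")
        if len(self.band_fractions) != len(self.informative_band_centers):
            raise InvalidDesignError("one band fraction per band center is required")
        if self.noise_sd_noisy <= self.noise_sd_clean:
            raise InvalidDesignError(
                "noise_sd_noisy must exceed noise_sd_clean (the CV filter "
                "would have nothing to find)"
            )
        if not 0.0 <= self.loss_fraction < 1.0:
            raise InvalidDesignError("loss_fraction must lie in [0, 1)")
        if self.background_shape is not None:
            bg = np.asarray(self.background_shape, dtype=float)
            if bg.shape != wl.shape or np.any(bg <= 0):
                raise InvalidDesignError(
                    "background_shape must be positive and match the grid"
                )
            object.__setattr__(self, "background_shape", bg)

    def with_(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SpectraDataset:
    """Replicate transflectance spectra plus reference concentrations.

    ``transflectance`` has shape (samples, acquisitions, channels), in ut.
    """

    transflectance: np.ndarray
    wavelengths: np.ndarray
    concentrations: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.transflectance, dtype=float)
        if t.ndim != 3:
            raise InvalidDesignError("transflectance must be (samples, acquisitions, channels)")
        if np.any(t <= 0):
            raise InvalidDesignError("transflectance values must be strictly positive")
        if t.shape[0] != len(self.concentrations):
            raise InvalidDesignError("one concentration per sample is required")
        if t.shape[2] != len(self.wavelengths):
            raise InvalidDesignError("channel axis must match the wavelength grid")
        self.transflectance = t
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.transflectance.shape[0]

    @property
    def n_acquisitions(self) -> int:
        return self.transflectance.shape[1]

    @property
    def n_channels(self) -> int:
        return self.transflectance.shape[2]


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    planted_informative_channels: np.ndarray
    planted_noisy_channels: np.ndarray
    band_center_channels: np.ndarray
    scatter_offsets: np.ndarray  # a, shape (samples, acquisitions)
    scatter_slopes: np.ndarray  # b, shape (samples, acquisitions)
    band_weights: np.ndarray  # compound fractions, shape (samples, bands)
    noiseless_transflectance: np.ndarray
    true_concentrations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.intersect1d(
            self.planted_informative_channels, self.planted_noisy_channels
        ).size:
            raise InvalidDesignError(
                "informative and noisy channel sets must be disjoint"
            )


def make_base_concentrations(n: int, c_min: float, c_max: float) -> np.ndarray:
    """``n`` evenly spaced concentrations from ``c_min`` to ``c_max``, rounded
    half-away-from-zero to integer mg/kg."""
    if n < 2:
        raise InvalidDesignError("need at least two base concentrations")
    if c_min >= c_max:
        raise InvalidDesignError("c_min must be below c_max")
    raw = np.linspace(float(c_min), float(c_max), n)
    return np.sign(raw) * np.floor(np.abs(raw) + 0.5)


def blend_consecutive(concentrations: Sequence[float]) -> np.ndarray:
    """Interleave a sorted concentration series with midpoints of consecutive
    pairs (equal-volume blending), giving 2n-1 values."""
    c = np.asarray(concentrations, dtype=float)
    if c.ndim != 1 or c.size < 1:
        raise InvalidDesignError("concentrations must be a non-empty vector")
    if np.any(np.diff(c) < 0):
        raise InvalidDesignError("concentrations must be sorted ascending")
    out = np.empty(2 * c.size - 1)
    out[0::2] = c
    if c.size > 1:
        out[1::2] = 0.5 * (c[:-1] + c[1:])
    return out


def _background(config: GeneratorConfig) -> np.ndarray:
    if config.background_shape is not None:
        bg = config.background_shape
    else:
        wl = config.wavelengths
        bg = np.exp(
            -0.5 * ((wl - config.reference_wavelength) / config.background_width) ** 2
        )
    ref = np.argmin(np.abs(config.wavelengths - config.reference_wavelength))
    return bg / bg[ref]


def _band_profiles(config: GeneratorConfig) -> np.ndarray:
    """Sigmoidal shoulder per band: Gaussian CDF of width sigma, so the first
    derivative peaks exactly at the center wavelength; shape (bands, channels)."""
    wl = config.wavelengths
    centers = np.asarray(config.informative_band_centers, dtype=float)
    sigma = float(config.informative_band_widths)
    return ndtr((wl[None, :] - centers[:, None]) / sigma)


def _channel_noise_sd(config: GeneratorConfig) -> np.ndarray:
    wl = config.wavelengths
    lo, hi = config.noisy_band
    noisy = (wl >= lo) & (wl <= hi)
    return np.where(noisy, config.noise_sd_noisy, config.noise_sd_clean)


def generate_dataset(config: GeneratorConfig) -> tuple[SpectraDataset, GroundTruth]:
    """Generate a seeded replicate-spectra dataset and its ground truth.

    The lamp gain is set so the noiseless transflectance at the reference
    wavelength equals the power target; per-acquisition scatter and channel
    noise produce a spread at that wavelength of a few ut, comparable to a
    regulated halogen source.
    """
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths

    concs = make_base_concentrations(
        config.n_base_samples, config.conc_min, config.conc_max
    )
    if config.blend:
        concs = blend_consecutive(concs)
    n_samples = concs.size
    n_acq = config.n_acquisitions
    n_chan = wl.size
    n_bands = len(config.informative_band_centers)

    # latent compound split of the total polyphenol content
    fractions = np.asarray(config.band_fractions, dtype=float)
    fractions = fractions / fractions.sum()
    jitter = rng.normal(1.0, config.band_weight_sd, size=(n_samples, n_bands))
    weights = fractions[None, :] * np.clip(jitter, 0.05, None)
    weights /= weights.sum(axis=1, keepdims=True)
    compound = concs[:, None] * weights  # (samples, bands), mg/kg

    profiles = _band_profiles(config)  # (bands, channels)
    strengths = np.broadcast_to(
        np.asarray(config.informative_band_strengths, dtype=float), (n_bands,)
    )
    # chemical absorbance per sample
    a_chem = (compound * strengths[None, :]) @ profiles  # (samples, channels)

    # per-acquisition scatter: multiplicative slope b, additive offset a
    offsets = rng.normal(0.0, config.scatter_offset_sd, size=(n_samples, n_acq))
    slopes = rng.normal(1.0, config.scatter_slope_sd, size=(n_samples, n_acq))
    absorbance = (
        slopes[:, :, None] * a_chem[:, None, :] + offsets[:, :, None]
    )  # (samples, acquisitions, channels)

    background = _background(config)
    gain = config.power_target / (1.0 - config.loss_fraction)
    clean = gain * background[None, None, :] * (
        np.power(10.0, -absorbance) - config.loss_fraction
    )

    sd = _channel_noise_sd(config)
    if config.noise_correlation_length > 0:
        # stationary smooth noise: filter a padded white field and crop so
        # edge channels carry the same variance as interior ones
        pad = int(4 * config.noise_correlation_length) + 1
        wide = rng.standard_normal(
            size=(n_samples, n_acq, n_chan + 2 * pad)
        )
        wide = gaussian_filter1d(wide, config.noise_correlation_length, axis=2)
        noise = wide[:, :, pad:-pad]
        noise = noise / (noise.std(ddof=0) or 1.0)  # restore unit variance
    else:
        noise = rng.standard_normal(size=clean.shape)
    trans = np.clip(clean + noise * sd[None, None, :], TRANSFLECTANCE_FLOOR, None)

    # the reported reference values carry the chemical assay's error;
    # the spectra above reflect the true compound contents
    reported = concs + rng.normal(0.0, config.reference_noise_sd, size=n_samples)

    dataset = SpectraDataset(
        transflectance=trans,
        wavelengths=wl.copy(),
        concentrations=reported,
        metadata={
            "power_target": config.power_target,
            "seed": config.seed,
            "reference_wavelength": config.reference_wavelength,
            "grid": "uniform-nm",
        },
    )

    sigma = float(config.informative_band_widths)
    centers = np.asarray(config.informative_band_centers, dtype=float)
    informative = np.unique(
        np.nonzero(np.any(np.abs(wl[None, :] - centers[:, None]) <= sigma, axis=0))[0]
    )
    lo, hi = config.noisy_band
    noisy = np.nonzero((wl >= lo) & (wl <= hi))[0]
    truth = GroundTruth(
        planted_informative_channels=np.setdiff1d(informative, noisy),
        planted_noisy_channels=noisy,
        band_center_channels=np.array(
            [int(np.argmin(np.abs(wl - c))) for c in centers]
        ),
        scatter_offsets=offsets,
        scatter_slopes=slopes,
        band_weights=weights,
        noiseless_transflectance=np.clip(clean, TRANSFLECTANCE_FLOOR, None),
        true_concentrations=concs,
    )
    return dataset, truth


def recovery_study_config(seed: int = 0) -> GeneratorConfig:
    """Generator configuration for the wavelength-recovery study.

    A high-SNR variant of the default design: sharp polyphenol shoulders
    (sigma 4 nm, the narrowest feature the instrument line shape supports)
    and channel-correlated drift noise (correlation length 30 channels, the
    smooth baseline wobble that dominates a stabilized FT-NIR between
    acquisitions) instead of white detector noise.  Under the first
    derivative this is the regime in which the selected wavelengths localize
    most tightly around the planted centers.
    """
    return GeneratorConfig(
        informative_band_widths=4.0,
        informative_band_strengths=1e-5,
        seed=seed,
    )


def replicate_statistics(dataset: SpectraDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample, per-channel mean and SD (ddof=1) across acquisitions."""
    if dataset.n_acquisitions < 2:
        raise InsufficientReplicatesError(
            "replicate statistics require at least two acquisitions"
        )
    t = dataset.transflectance
    return t.mean(axis=1), t.std(axis=1, ddof=1)
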