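import numpy as np
import pytest

from nircal import GeneratorConfig, generate_dataset

#: channel spacing of the default 921-point grid, nm
GRID_STEP = 1700.0 / 920.0

#: base concentration series of the reference study design (mg/kg)
PRINTED_BASES = [1017, 1132, 1247, 1362, 1478, 1593, 1708, 1823, 1939, 2054, 2169]

#: the 21-sample series after pairwise equal-volume blending (mg/kg)
PRINTED_BLENDED = [
    1017, 1074, 1132, 1189, 1247, 1305, 1362, 1420, 1478, 1535, 1593,
    1650, 1708, 1766, 1823, 1881, 1939, 1996, 2054, 2112, 2169,
]


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded dataset with the default study design."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_config():
    """Generator settings with every random disturbance switched off.

    The tiny noisy-band SD keeps the required clean<noisy ordering while
    contributing nothing measurable.
    """
    return GeneratorConfig(
        noise_sd_clean=0.0,
        noise_sd_noisy=1e-30,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        band_weight_sd=0.0,
        reference_noise_sd=0.0,
        noise_correlation_length=0.0,
        loss_fraction=0.0,  # hardware losses make absorbance only nearly affine
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
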