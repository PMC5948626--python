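"""Generate a synthetic transflectance study and look at its structure.

Builds the default design: 11 base oils evenly spanning 1017-2169 mg/kg of
total polyphenols, blended pairwise to 21 samples, 10 acquisitions each
over 900-2600 nm with the lamp regulated to 400 ut at 1600 nm.
"""

import numpy as np

from nircal import GeneratorConfig, generate_dataset, save_dataset

config = GeneratorConfig(seed=0)
dataset, truth = generate_dataset(config)

print(f"samples x acquisitions x channels: {dataset.transflectance.shape}")
print(f"concentrations (mg/kg): {np.round(dataset.concentrations[:5], 1)} ...")

ref = np.argmin(np.abs(dataset.wavelengths - config.reference_wavelength))
at_ref = dataset.transflectance[:, :, ref]
print(
    f"transflectance at {config.reference_wavelength:.0f} nm: "
    f"mean {at_ref.mean():.2f} ut, SD {at_ref.std():.2f} ut "
    f"(target {config.power_target:.0f} ut)"
)
# The mean should sit on the lamp's power target; the SD is the combined
# effect of detector noise and acquisition-to-acquisition scatter.

noisy = truth.planted_noisy_channels
print(
    f"planted low-SNR band: {dataset.wavelengths[noisy[0]]:.0f}-"
    f"{dataset.wavelengths[noisy[-1]]:.0f} nm ({noisy.size} channels)"
)
print(f"planted feature centers (nm): {config.informative_band_centers}")

out = save_dataset(dataset, "scratch/example_dataset", truth=truth, config=config)
print(f"written to {out}/ (spectra.csv, concentrations.csv, groundtruth.json)")
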