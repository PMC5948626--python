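# Methods

`nircal` couples a generative model of an olive-oil NIR transflectance study
with the calibration chain that such studies use (CV band filter,
absorbance, SNV/MSC/Savitzky–Golay pretreatment, ANOVA wavelength screening,
stepwise multilinear regression, LOOCV/holdout validation). This note
records the model, its parameters and defaults, the numerical choices, and
what the synthetic data does and does not establish.

## Generative model of the study

**Design.** Eleven base oils with total polyphenol contents evenly spaced
over [1017, 2169] mg/kg (rounded half-away-from-zero to integer mg/kg) are
blended pairwise in equal volumes, interleaving exact midpoints to give 21
samples. Each sample is measured 10 times.

**Spectra.** The wavelength grid is uniform, 921 channels over 900–2600 nm
(≈1.85 nm/channel; the real instrument's 8 cm⁻¹ resolution implies a
non-uniform nm grid — uniformity is a declared simplification, recorded in
the dataset metadata). Per wavelength the detector obeys the energy balance
P_r = P_t − P_abs − L: transmitted lamp power minus sample absorption minus
hardware losses. With Beer-law absorbance A(υ),

    T(υ) = gain · S(υ) · (10^(−A(υ)) − loss_fraction) + ε(υ),

clamped at 10⁻⁶ ut so log10 stays defined. S(υ) is the lamp/transmission
profile, a Gaussian of width 600 nm peaking at the 1600 nm reference
wavelength and normalized there; the gain is set so the noiseless
transflectance at 1600 nm equals the power target (200/300/400 ut — the
acquisition groups S1–S3). With the default disturbances the group mean at
1600 nm lands on the target with an SD of ≈3 ut, the spread a regulated
halogen source exhibits.

**Chemistry.** Total polyphenols are modelled as three latent compound
groups, one per planted feature, with per-sample proportions jittered
around equal thirds (`band_fractions`, `band_weight_sd = 0.20`, truncated
positive and renormalized). Each group contributes a sigmoidal absorption
shoulder — a Gaussian CDF of width σ = 15 nm by default — centred at 1830,
1917 and 2189 nm, with height `informative_band_strengths`
(3×10⁻⁵ AU per mg/kg) times the group's content. A shoulder's first
derivative is a Gaussian peaked exactly at the named centre, so under
derivative pretreatment the planted wavelengths are the points of maximal
concentration sensitivity. The composition jitter keeps the three features
from being perfectly collinear in the total, which is what makes a
three-term model identifiable at all: with `band_weight_sd = 0` any single
feature channel is an exact affine function of the total (the
recoverability invariant the tests exercise).

**Disturbances.**

* Per-acquisition scatter: absorbance is taken as b·A + a with
  b ~ N(1, 0.02) and a ~ N(0, 0.002) — the multiplicative/offset class of
  artefact that SNV and MSC are built to remove.
* Channel noise: additive, SD 2.5 ut in the clean region and 25 ut inside
  the designated low-SNR band 2240–2600 nm (the 10× contrast the CV filter
  must find). By default the noise is smooth along the channel axis
  (Gaussian correlation length 30 channels), modelling the baseline
  wobble/drift that dominates a stabilized FT-NIR between acquisitions; it
  is generated on a padded axis so edge channels are stationary.
  `noise_correlation_length = 0` gives white detector noise instead, and is
  the variant used by the averaging and lamp-power studies, which probe
  exactly the uncorrelated component.
* Reference-assay error: the reported concentrations are the true values
  plus N(0, 80 mg/kg) noise, the error floor a wet-chemistry polyphenol
  assay leaves in the reference method. The spectra reflect the true
  values. This term is essential to realistic behaviour of the stepwise
  regression: without it the residual is pure channel noise, which
  neighbouring (noise-sharing) channels can cancel, and the selection runs
  to its degrees-of-freedom guard (18 terms at N = 21) instead of stopping
  at a few chemically meaningful wavelengths. With it, the default study
  lands on the published scale of such calibrations (three components,
  R²c ≈ 0.91, LOOCV R²v ≈ 0.87, RMSEV ≈ 10 % of the concentration range).

`recovery_study_config()` is the high-SNR variant used by the
wavelength-recovery study: sharper shoulders (σ = 4 nm, about the narrowest
feature the instrument line shape supports) and weaker strength
(1×10⁻⁵ AU per mg/kg), which is the regime where the selected wavelengths
localize most tightly around the planted centres.

## Pipeline and statistical details

* **CV filter.** CV is computed per sample across acquisitions on raw
  transflectance (the mean in absorbance units is near zero, so a CV there
  is ill-posed), then averaged over samples without weights; a pooled
  variant is available. The threshold is the mean CV; removal requires
  strictly exceeding it, so an all-equal CV vector removes nothing.
* **Pretreatment order** is fixed: absorbance → band removal → (SNV | MSC |
  SG | none). SG uses least-squares convolution coefficients
  (`scipy.signal.savgol_coeffs`); edge channels without a full window are
  dropped rather than padded, and derivatives are per channel index.
* **ANOVA screening** splits at the median (samples at the median go to the
  low class: 11 low / 10 high at N = 21), uses the two-class F statistic
  with df (1, N−2), keeps p < 0.05 up to 100 channels ranked by descending
  F with ties broken toward the lower channel index. No multiple-testing
  correction is applied — deliberately permissive screening, with the
  caveat that ≈5 % of pure-noise channels pass. Channels whose variation
  sits at float-rounding precision are reported as null rather than letting
  a vanishing within-class sum of squares produce an arbitrary F.
* **SMLR.** Forward entry adds the smallest-p candidate (ties: largest F,
  then lowest index) if p < p_enter = 0.05; backward elimination removes
  coefficients with p > p_remove = 0.10, largest first; iteration stops
  when neither rule fires or N − m − 1 ≤ 1. p_remove ≥ p_enter is enforced
  (entry needs p below the threshold, removal needs p above it, so equality
  cannot cycle). Candidates that do not increase the design rank are
  rejected; an exactly explained response stops entry via a machine-scale
  tolerance on the residual sum of squares. Models store wavelengths, not
  indices, so they survive band-filter changes.
* **Validation.** RMSEC/R²c always come from the full-data fit, so the
  calibration columns are identical across validation modes. By default the
  band filter, screening and stepwise channel choice are done once on all
  samples and only coefficients are refit per fold — the common chemometric
  practice, which leaks selection information into RMSEV;
  `selection_in_fold=True` redoes selection inside every fold. Holdout
  training takes ⌊N/2⌋ samples (validation gets the larger half at odd N).
  A fold smaller than the model falls back to minimum-norm least squares.
* **Averaging** uses the first n captures (seeded random subsets
  optional) and anchors the mean on the first capture, which makes
  averaging exact for identical replicates and cancellation-free for nearly
  identical ones.

## What the generator does not emulate

No temperature, moisture or turbidity effects; no wavelength-dependent
instrument line shape; no drift between samples (acquisitions are i.i.d.
given the sample); no nonlinearity between absorbance and concentration
beyond the loss-fraction term. Passing tests therefore demonstrate the
correctness and statistical behaviour of the *pipeline*, not the field
performance of a real probe.

## Limits of stepwise wavelength recovery

Two structural findings from this package's simulations are worth stating
because they bound what any test of this pipeline can show.

First, with ~900 channels screened at α = 0.05, about 36 pure-noise
channels reach the stepwise stage, and the minimum-p forward entry over k
independent null candidates fires with probability ≈ 1 − 0.95^k. "Exactly
three terms" is therefore a ≲15 % event under independent channel noise no
matter how small the noise amplitude is (the partial-F statistic is
scale-free in the candidate). Channel-correlated noise collapses the null
candidates to a few effective dimensions and makes three-term models the
norm — but it simultaneously removes the per-channel noise penalty that
pins the within-feature argmax, and the 11-point derivative kernel spreads
any feature's response over ±4–5 channels, so the selected wavelength then
wanders several channels around the true centre. Pinning selection to ±2
channels would need per-channel noise large enough to violate an R²v ≥ 0.8
budget. On the recovery fixture the package measures ≈40–60 % of seeds
giving exactly three terms and ≈10–25 % additionally localizing all three
within ±2 channels (the acceptance script reports both rates); one
acceptance test asserts a stricter 90 % joint rate and is expected to fail.
The practical reading: stepwise selection reliably finds the informative
*regions*, but its exact wavelength set and count are unstable at N = 21 —
consistent with the wide literature on stepwise instability.

Second, for a purely linear calibration every Savitzky–Golay window yields
channels that are linear functionals of the spectrum, so widening the
window monotonically trades nothing for noise reduction; a stable interior
optimum of RMSEV over window size does not exist in this model. The window
study therefore demonstrates the under-smoothing penalty (the smallest
window is clearly worst) rather than an interior argmin. Interior optima in
real data plausibly come from effects outside this model (nonlinearity,
feature loss at the grid edge, baseline artefacts).

## Problem sizes used in tests and the acceptance script

Module tests run tens of seeds per property; the acceptance-style checks
use 50 seeds for band-removal and wavelength-recovery rates, 100 seeded
datasets for the 1/√n noise-scaling law, and 25 matched seeds for the
averaging and lamp-power trends. The acceptance script uses 10–60 seeds
per quantity, chosen so a full run completes in well under a minute.
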