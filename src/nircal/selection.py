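"""One-way ANOVA wavelength screening.

Samples are split into high/low polyphenol classes; each channel is scored
with a one-way ANOVA F statistic (df = (k-1, N-k), k = 2 classes).  Channels
with p below the significance level are retained, ranked by descending F and
truncated at a cap.  No multiple-testing correction is applied: screening
uses the raw per-channel p value, which is permissive by design (the cap and
the downstream stepwise regression do the real pruning).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist

from .errors import DegenerateSplitError, EmptySelectionError, InvalidParametersError
from .preprocess import AbsorbanceMatrix

__all__ = ["WavelengthSelection", "split_classes", "anova_f", "anova_f_channels",
           "select_wavelengths"]


@dataclass
class WavelengthSelection:
    """Per-channel F/p values and the ranked retained channel indices."""

    labels: np.ndarray
    f_values: np.ndarray
    p_values: np.ndarray
    selected_indices: np.ndarray  # descending F, ties broken by lower index
    selected_wavelengths: np.ndarray
    alpha: float
    cap: int

    @property
    def n_selected(self) -> int:
        return self.selected_indices.size


def split_classes(concentrations, rule="median") -> np.ndarray:
    """Binary high/low class labels (1 = high polyphenol content).

    ``rule="median"`` puts samples at or below the median in the low class;
    a numeric rule is a fixed concentration threshold (low: value <= t).
    """
    c = np.asarray(concentrations, dtype=float)
    if c.size < 2:
        raise DegenerateSplitError("need at least two samples to split")
    if isinstance(rule, str):
        if rule != "median":
            raise InvalidParametersError(f"unknown split rule: {rule!r}")
        t = float(np.median(c))
    else:
        t = float(rule)
    labels = (c > t).astype(int)
    if labels.min() == labels.max():
        raise DegenerateSplitError(
            f"threshold {t} leaves one class empty"
        )
    return labels


def anova_f(values, labels) -> tuple[float, float, tuple[int, int]]:
    """One-way ANOVA F test of a single channel against binary class labels.

    Returns (F, p, (df_between, df_within)).  Zero within-class variance with
    distinct class means reports F = +inf, p = 0.
    """
    v = np.asarray(values, dtype=float)
    f, p = anova_f_channels(v[:, None], labels)
    n = v.size
    return float(f[0]), float(p[0]), (1, n - 2)


def anova_f_channels(values, labels) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-class one-way ANOVA over channels (columns)."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if x.ndim != 2 or y.shape != (x.shape[0],):
        raise InvalidParametersError("values must be (samples, channels) with one label per sample")
    groups = np.unique(y)
    if groups.size != 2:
        raise DegenerateSplitError("exactly two classes are required")
    n = x.shape[0]
    if n < 3:
        raise InvalidParametersError("ANOVA needs at least three samples")
    x0, x1 = x[y == groups[0]], x[y == groups[1]]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    gm = x.mean(axis=0)
    ssb = x0.shape[0] * (m0 - gm) ** 2 + x1.shape[0] * (m1 - gm) ** 2
    ssw = ((x0 - m0) ** 2).sum(axis=0) + ((x1 - m1) ** 2).sum(axis=0)
    df_w = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ssw > 0, ssb / (ssw / df_w), np.where(ssb > 0, np.inf, 0.0))
    p = np.where(np.isinf(f), 0.0, f_dist.sf(np.where(np.isinf(f), 0.0, f), 1, df_w))
    # channels whose variation sits at float rounding precision carry no
    # analytical information; report them as null rather than letting a
    # vanishing within-class SS produce an arbitrarily large F
    degenerate = x.std(axis=0) <= 1e-12 * np.maximum(1.0, np.abs(gm))
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    return f, p


def select_wavelengths(
    spectra: AbsorbanceMatrix,
    labels,
    alpha: float = 0.05,
    cap: int = 100,
) -> WavelengthSelection:
    """Retain channels with p < alpha, ranked by descending F, capped.

    Ties in F are broken toward the lower channel index for determinism.
    """
    if cap < 1:
        raise InvalidParametersError("cap must be positive")
    labels = np.asarray(labels)
    f, p = anova_f_channels(spectra.values, labels)
    candidates = np.nonzero(p < alpha)[0]
    if candidates.size == 0:
        raise EmptySelectionError(
            f"no channel significant at alpha={alpha}; consider relaxing alpha"
        )
    # stable sort on -F keeps lower indices first among ties
    order = candidates[np.argsort(-f[candidates], kind="stable")][:cap]
    return WavelengthSelection(
        labels=labels,
        f_values=f,
        p_values=p,
        selected_indices=order,
        selected_wavelengths=spectra.wavelengths[order],
        alpha=alpha,
        cap=cap,
    )
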