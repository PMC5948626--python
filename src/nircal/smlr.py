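"""Stepwise multilinear regression (SMLR) for wavelength selection.

Forward entry / backward elimination on partial-F significance:

* forward — among channels not in the model, compute the partial F test of
  adding each one (equal to the squared t statistic of its coefficient in
  the enlarged fit); add the channel with the smallest p if p < p_enter;
* backward — remove any included channel whose coefficient p exceeds
  p_remove, largest p first;
* stop when neither rule fires or the residual degrees of freedom are
  exhausted (N - m - 1 <= 1).

The final model is the familiar chemometric calibration form
``y_hat = b0 + sum_k b_k * x_k`` over a handful of selected channels.
Requiring p_remove >= p_enter prevents add/remove cycles.  Forward ties are
broken by smallest p, then largest F, then lowest channel index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .errors import (
    CollinearDesignError,
    InvalidParametersError,
    ModelMismatchError,
)
from .preprocess import AbsorbanceMatrix

__all__ = ["OLSFit", "SMLRModel", "fit_ols", "partial_f_test", "smlr_fit", "predict"]

_MAX_STEPS = 500


@dataclass
class OLSFit:
    """Ordinary least squares fit with an implicit intercept column."""

    intercept: float
    coefficients: np.ndarray
    residual_ss: float
    se_intercept: float
    se_coefficients: np.ndarray
    df_resid: int
    n: int

    def coefficient_p_values(self) -> np.ndarray:
        """Two-sided p values of the non-intercept coefficients."""
        if self.coefficients.size == 0:
            return np.empty(0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(self.coefficients) / self.se_coefficients
        p = np.where(
            self.se_coefficients > 0,
            2.0 * t_dist.sf(np.where(self.se_coefficients > 0, t, 0.0), self.df_resid),
            np.where(self.coefficients != 0, 0.0, 1.0),
        )
        return p


@dataclass
class SMLRModel:
    """Stepwise-selected linear calibration model.

    ``terms`` is an ordered list of (channel index, wavelength nm,
    coefficient); wavelengths, not indices, identify terms at prediction
    time so models survive band-filter changes.
    """

    intercept: float
    terms: list[tuple[int, float, float]]
    p_enter: float
    p_remove: float
    trace: list[dict] = field(default_factory=list)
    intercept_only_warning: bool = False

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([w for _, w, _ in self.terms])

    @property
    def channel_indices(self) -> np.ndarray:
        return np.array([k for k, _, _ in self.terms], dtype=int)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([b for _, _, b in self.terms])


def fit_ols(design: np.ndarray, response: np.ndarray) -> OLSFit:
    """Least-squares fit of ``response`` on an intercept plus the design
    columns, with standard errors from the unbiased residual variance."""
    x = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    if x.size == 0:
        x = np.empty((y.size, 0))
    if x.shape[0] != y.size:
        raise InvalidParametersError("design rows must match the response length")
    n, m = x.shape
    if n <= m + 1:
        raise InvalidParametersError(
            f"need more samples ({n}) than parameters ({m + 1})"
        )
    xd = np.column_stack([np.ones(n), x])
    beta, _, rank, _ = np.linalg.lstsq(xd, y, rcond=None)
    if rank < m + 1:
        dep = [
            j - 1
            for j in range(1, m + 1)
            if np.linalg.matrix_rank(np.delete(xd, j, axis=1)) == rank
        ]
        raise CollinearDesignError(
            f"design matrix is rank deficient (rank {rank} < {m + 1}); "
            f"dependent columns include {dep[:5]}"
        )
    resid = y - xd @ beta
    rss = float(resid @ resid)
    df = n - m - 1
    sigma2 = rss / df
    cov = sigma2 * np.linalg.pinv(xd.T @ xd)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return OLSFit(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        residual_ss=rss,
        se_intercept=float(se[0]),
        se_coefficients=se[1:],
        df_resid=df,
        n=n,
    )


def partial_f_test(
    design: np.ndarray, candidate: np.ndarray, response: np.ndarray
) -> tuple[float, float]:
    """Partial F test of adding one column to an existing design.

    F = (RSS_without - RSS_with) / (RSS_with / (N - m_with - 1)), compared
    against F(1, N - m_with - 1).  A zero enlarged residual (exact fit) is a
    perfect-fit signal: (inf, 0).
    """
    x = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    z = np.asarray(candidate, dtype=float)
    if x.size == 0:
        x = np.empty((y.size, 0))
    n = y.size
    without = np.column_stack([np.ones(n), x])
    with_ = np.column_stack([without, z])
    b0, _, _, _ = np.linalg.lstsq(without, y, rcond=None)
    b1, _, rank1, _ = np.linalg.lstsq(with_, y, rcond=None)
    if rank1 < with_.shape[1]:  # candidate adds no direction to the design
        return 0.0, 1.0
    rss0 = float(np.sum((y - without @ b0) ** 2))
    rss1 = float(np.sum((y - with_ @ b1) ** 2))
    df = n - with_.shape[1]
    if df < 1:
        raise InvalidParametersError("no residual degrees of freedom for the partial test")
    tol = 1e-20 * max(1.0, float(y @ y))
    if rss0 <= tol:  # nothing left to explain
        return 0.0, 1.0
    if rss1 <= tol:
        return np.inf, 0.0
    f = max(rss0 - rss1, 0.0) / (rss1 / df)
    return float(f), float(f_dist.sf(f, 1, df))


def smlr_fit(
    spectra: AbsorbanceMatrix | np.ndarray,
    response: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    wavelengths: np.ndarray | None = None,
) -> SMLRModel:
    """Run the stepwise forward/backward selection and return the model.

    ``spectra`` is an AbsorbanceMatrix (typically already restricted to the
    ANOVA-selected channels) or a plain (samples, channels) array with an
    explicit ``wavelengths`` vector.
    """
    if isinstance(spectra, AbsorbanceMatrix):
        x_all = spectra.values
        wl = spectra.wavelengths
    else:
        x_all = np.atleast_2d(np.asarray(spectra, dtype=float))
        wl = (
            np.asarray(wavelengths, dtype=float)
            if wavelengths is not None
            else np.arange(x_all.shape[1], dtype=float)
        )
    y = np.asarray(response, dtype=float)
    n, n_chan = x_all.shape
    if n < 3:
        raise InvalidParametersError("stepwise regression needs at least three samples")
    if y.size != n:
        raise InvalidParametersError("one response value per sample is required")
    if p_remove < p_enter:
        raise InvalidParametersError(
            "p_remove must be at least p_enter to prevent add/remove cycles"
        )

    included: list[int] = []
    trace: list[dict] = []

    for _ in range(_MAX_STEPS):
        acted = False

        # forward entry, only while residual df would remain after the add
        if n - (len(included) + 1) - 1 > 1:
            base = x_all[:, included]
            best = None  # (p, -f, index)
            for k in range(n_chan):
                if k in included:
                    continue
                f, p = partial_f_test(base, x_all[:, k], y)
                key = (p, -f, k)
                if best is None or key < best[0]:
                    best = (key, k, f, p)
            if best is not None and best[3] < p_enter:
                _, k, f, p = best
                included.append(k)
                trace.append(
                    {"action": "add", "channel": int(k), "wavelength": float(wl[k]),
                     "F": f, "p": p,
                     "rss": fit_ols(x_all[:, included], y).residual_ss}
                )
                acted = True

        # backward elimination: drop the worst over-threshold coefficient
        while len(included) > 0:
            fit = fit_ols(x_all[:, included], y)
            pvals = fit.coefficient_p_values()
            worst = int(np.argmax(pvals))
            if pvals[worst] <= p_remove:
                break
            k = included.pop(worst)
            trace.append(
                {"action": "remove", "channel": int(k), "wavelength": float(wl[k]),
                 "F": float((fit.coefficients[worst] / fit.se_coefficients[worst]) ** 2)
                 if fit.se_coefficients[worst] > 0 else np.inf,
                 "p": float(pvals[worst]),
                 "rss": fit_ols(x_all[:, [i for i in included]], y).residual_ss},
            )
            acted = True

        if not acted:
            break

    final = fit_ols(x_all[:, included], y)
    terms = [
        (int(k), float(wl[k]), float(b))
        for k, b in zip(included, final.coefficients)
    ]
    return SMLRModel(
        intercept=final.intercept,
        terms=terms,
        p_enter=p_enter,
        p_remove=p_remove,
        trace=trace,
        intercept_only_warning=(len(terms) == 0),
    )


def predict(model: SMLRModel, spectra: AbsorbanceMatrix) -> np.ndarray:
    """Evaluate ``y_hat = b0 + sum_k b_k x_k``, matching terms by wavelength."""
    yhat = np.full(spectra.n_samples, model.intercept)
    for _, w, b in model.terms:
        j = np.nonzero(np.isclose(spectra.wavelengths, w, rtol=0, atol=1e-6))[0]
        if j.size == 0:
            raise ModelMismatchError(
                f"model wavelength {w} nm is absent from the spectra"
            )
        yhat = yhat + b * spectra.values[:, j[0]]
    return yhat
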