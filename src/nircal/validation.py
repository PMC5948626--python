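"""Calibration/validation metrics and resampling schemes.

RMSE and the determination coefficient R^2 (which may be negative for a
model worse than the response mean), leave-one-out cross-validation
(LOOCV, one fold per sample) and a seeded 50/50 random holdout split.

Both resampling schemes here refit the *coefficients* of a fixed set of
selected channels per fold; whether the wavelength selection itself is
redone inside each fold is decided one level up, in the pipeline (see
``selection_in_fold`` there).  RMSEC/R2c always come from the full-data
fit, so calibration rows are identical across validation modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FoldFitError, InvalidFractionError, InvalidParametersError, NircalError
from .smlr import fit_ols

__all__ = ["ValidationReport", "rmse", "r2", "loocv", "holdout", "holdout_split"]


@dataclass
class ValidationReport:
    """Table-row summary of one calibration/validation run."""

    rmsec: float
    r2c: float
    rmsev: float
    r2v: float
    n_components_after_filter: int = 0
    n_components_after_regression: int = 0
    preprocessing: str = ""
    validation: str = ""
    observed: np.ndarray = field(default_factory=lambda: np.empty(0))
    predicted: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.rmsec < 0 or self.rmsev < 0:
            raise InvalidParametersError("RMSE cannot be negative")
        if len(self.observed) != len(self.predicted):
            raise InvalidParametersError("observed/predicted pairs must align")


def rmse(observed, predicted) -> float:
    """Root mean square error, in the units of the response."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 1:
        raise InvalidParametersError("observed and predicted must have equal nonzero length")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r2(observed, predicted) -> float:
    """Determination coefficient 1 - SS_res/SS_tot (can be negative)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise InvalidParametersError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidParametersError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _fit_predict(x_train, y_train, x_eval):
    x_train = np.atleast_2d(x_train)
    x_eval = np.atleast_2d(x_eval)
    if x_train.shape[0] > x_train.shape[1] + 1:
        fit = fit_ols(x_train, y_train)
        return fit.intercept + x_eval @ fit.coefficients
    # fold smaller than the model: minimum-norm least squares still defines
    # the refit coefficients (and the held-out prediction)
    xd = np.column_stack([np.ones(len(y_train)), x_train])
    beta = np.linalg.lstsq(xd, y_train, rcond=None)[0]
    return np.column_stack([np.ones(x_eval.shape[0]), x_eval]) @ beta


def loocv(design: np.ndarray, response: np.ndarray) -> ValidationReport:
    """Leave-one-out cross-validation of a linear model on fixed channels.

    N folds: each refits the coefficients on N-1 samples and predicts the
    held-out one.  RMSEV/R2v are computed over the N held-out predictions;
    RMSEC/R2c come from the full-data fit.
    """
    x = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    n = y.size
    if n < 3:
        raise InvalidParametersError("LOOCV needs at least three samples")
    full = fit_ols(x, y)
    calib = full.intercept + x @ full.coefficients
    held_out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            held_out[i] = _fit_predict(x[keep], y[keep], x[i : i + 1])[0]
        except NircalError as exc:
            raise FoldFitError(f"LOOCV fold for sample {i} failed: {exc}") from exc
    return ValidationReport(
        rmsec=rmse(y, calib),
        r2c=r2(y, calib),
        rmsev=rmse(y, held_out),
        r2v=r2(y, held_out),
        n_components_after_regression=x.shape[1],
        validation="LOOCV",
        observed=y.copy(),
        predicted=held_out,
    )


def holdout_split(n: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random train/validation partition.

    ``fraction`` is the nominal training share; with odd N at 0.5 the
    training set takes the smaller half (floor), validation the larger.
    """
    if not 0.0 < fraction < 1.0:
        raise InvalidFractionError("holdout fraction must lie in (0, 1)")
    n_train = int(np.floor(n * fraction))
    if n_train < 2 or n - n_train < 2:
        raise InvalidFractionError(
            f"fraction {fraction} leaves a partition with fewer than two samples"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def holdout(
    design: np.ndarray,
    response: np.ndarray,
    fraction: float = 0.5,
    seed: int = 0,
) -> ValidationReport:
    """Random holdout validation on fixed channels.

    Coefficients are refit on the training partition and scored on the
    disjoint validation partition; RMSEC/R2c come from the full-data fit.
    """
    x = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float)
    train, valid = holdout_split(y.size, fraction, seed)
    full = fit_ols(x, y)
    calib = full.intercept + x @ full.coefficients
    pred = _fit_predict(x[train], y[train], x[valid])
    return ValidationReport(
        rmsec=rmse(y, calib),
        r2c=r2(y, calib),
        rmsev=rmse(y[valid], pred),
        r2v=r2(y[valid], pred),
        n_components_after_regression=x.shape[1],
        validation="HOLDOUT",
        observed=y[valid].copy(),
        predicted=np.asarray(pred),
    )
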