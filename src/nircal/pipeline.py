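"""End-to-end calibration pipeline and the acquisition-parameter studies.

The pipeline chains the stages in a fixed order:

    transflectance replicates
      -> CV noisy-band detection (on raw replicates)
      -> acquisition averaging
      -> absorbance conversion
      -> band removal
      -> pretreatment (none | SNV | MSC | SG)
      -> ANOVA wavelength screening (high/low class split)
      -> stepwise multilinear regression
      -> LOOCV or random holdout validation

Studies built on top of it: preprocessing comparison (a results table with
one row per pretreatment x validation mode), the SG window-size sweep, the
lamp-power sweep (datasets acquired at different transflectance targets)
and the acquisition-count averaging sweep.

Wavelength selection scope: by default the band filter, ANOVA screen and
stepwise channel choice are done once on all samples and only the model
coefficients are refit per validation fold.  This mirrors common
chemometric practice but leaks selection information into the validation
error; ``selection_in_fold=True`` redoes screening and stepwise selection
inside every fold (the band filter, which never sees the response, stays
global).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .datasets import SpectraDataset
from .errors import InvalidParametersError, NircalError
from .preprocess import (
    AbsorbanceMatrix,
    BandFilterResult,
    cv_per_wavelength,
    msc,
    remove_noisy_bands,
    savitzky_golay,
    snv,
    to_absorbance,
)
from .selection import WavelengthSelection, select_wavelengths, split_classes
from .smlr import SMLRModel, fit_ols, smlr_fit
from .validation import ValidationReport, holdout_split, loocv, r2, rmse

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "ExperimentGrid",
    "run_grid",
    "average_acquisitions",
    "run_pipeline",
    "preprocessing_table",
    "sweep_sg_window",
    "sweep_power",
    "sweep_acquisitions",
    "config_digest",
]

_PREPROCESSING_LABELS = {
    "none": "ABS",
    "snv": "ABS+SNV",
    "msc": "ABS+MSC",
    "sg": "ABS+SG",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of one pipeline run."""

    preprocessing: str = "sg"
    sg_window: int = 11
    sg_degree: int = 2
    sg_derivative: int = 1
    cv_filter: bool = True
    cv_method: str = "mean"
    n_acquisitions: int | None = None  # None = average all captures
    randomize_acquisitions: bool = False
    split_rule: object = "median"
    alpha: float = 0.05
    cap: int = 100
    p_enter: float = 0.05
    p_remove: float = 0.10
    validation: str = "loocv"
    holdout_fraction: float = 0.5
    selection_in_fold: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preprocessing not in _PREPROCESSING_LABELS:
            raise InvalidParametersError(
                f"unknown preprocessing {self.preprocessing!r}; "
                f"choose from {sorted(_PREPROCESSING_LABELS)}"
            )
        if self.validation not in ("loocv", "holdout"):
            raise InvalidParametersError("validation must be 'loocv' or 'holdout'")

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ExperimentGrid:
    """Axes of the acquisition-parameter studies.

    Each axis drives one study: pretreatments and validation modes fill the
    results table, `sg_windows` the window sweep, `power_targets` the lamp
    groups, `acquisition_counts` the averaging sweep.  `seeds` are the
    replicate generator seeds.
    """

    preprocessing_methods: tuple[str, ...] = ("none", "snv", "msc", "sg")
    sg_windows: tuple[int, ...] = tuple(range(5, 22, 2))
    power_targets: tuple[float, ...] = (200.0, 300.0, 400.0)
    acquisition_counts: tuple[int, ...] = tuple(range(1, 11))
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        for name in (
            "preprocessing_methods",
            "sg_windows",
            "power_targets",
            "acquisition_counts",
            "seeds",
        ):
            if len(getattr(self, name)) == 0:
                raise InvalidParametersError(f"experiment axis {name} is empty")
        unknown = set(self.preprocessing_methods) - set(_PREPROCESSING_LABELS)
        if unknown:
            raise InvalidParametersError(f"unknown preprocessing methods: {sorted(unknown)}")
        if any(w % 2 == 0 or w < 3 for w in self.sg_windows):
            raise InvalidParametersError("SG windows must be odd and >= 3")
        if any(n < 1 for n in self.acquisition_counts):
            raise InvalidParametersError("acquisition counts must be positive")


def run_grid(
    grid: ExperimentGrid,
    make_dataset,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Run every study axis of a grid.

    ``make_dataset(seed, power_target)`` must return a
    :class:`~nircal.datasets.SpectraDataset`; results of each axis are
    concatenated over seeds with a ``seed`` column, so aggregation is
    order-independent.
    """
    config = config or PipelineConfig()
    tables: dict[str, list[pd.DataFrame]] = {
        "preprocessing": [],
        "sg_window": [],
        "power": [],
        "acquisitions": [],
    }
    for seed in grid.seeds:
        ds = make_dataset(seed, grid.power_targets[-1])
        if max(grid.acquisition_counts) > ds.n_acquisitions:
            raise InvalidParametersError(
                "grid acquisition counts exceed the dataset's acquisitions"
            )
        for name, df in (
            ("preprocessing", preprocessing_table(ds, config, grid.preprocessing_methods)),
            ("sg_window", sweep_sg_window(ds, grid.sg_windows, config)),
            (
                "power",
                sweep_power(
                    {t: make_dataset(seed, t) for t in grid.power_targets}, config
                ),
            ),
            ("acquisitions", sweep_acquisitions(ds, grid.acquisition_counts, config)),
        ):
            tables[name].append(df.assign(seed=seed))
    return {name: pd.concat(parts, ignore_index=True) for name, parts in tables.items()}


def config_digest(config: PipelineConfig) -> str:
    """Short stable hash of a pipeline configuration (embedded in reports)."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    report: ValidationReport
    model: SMLRModel
    selection: WavelengthSelection
    band_filter: BandFilterResult | None
    absorbance: AbsorbanceMatrix
    config: PipelineConfig


def average_acquisitions(
    dataset: SpectraDataset,
    n: int,
    seed: int | None = None,
    randomize: bool = False,
) -> SpectraDataset:
    """Collapse replicates to one spectrum per sample: the mean of ``n``
    acquisitions (the first ``n`` in stored order, or a seeded random subset)."""
    if not 1 <= n <= dataset.n_acquisitions:
        raise InvalidParametersError(
            f"cannot average {n} of {dataset.n_acquisitions} acquisitions"
        )
    if randomize:
        rng = np.random.default_rng(seed)
        idx = rng.choice(dataset.n_acquisitions, size=n, replace=False)
    else:
        idx = np.arange(n)
    # anchored mean: exact when replicates are identical, and free of
    # cancellation for nearly identical ones
    sub = dataset.transflectance[:, idx, :]
    anchor = sub[:, :1, :]
    mean = anchor + (sub - anchor).mean(axis=1, keepdims=True)
    return SpectraDataset(
        transflectance=mean,
        wavelengths=dataset.wavelengths.copy(),
        concentrations=dataset.concentrations.copy(),
        metadata={**dataset.metadata, "averaged_acquisitions": int(n)},
    )


def _pretreat(matrix: AbsorbanceMatrix, config: PipelineConfig) -> AbsorbanceMatrix:
    if config.preprocessing == "none":
        return matrix
    if config.preprocessing == "snv":
        return snv(matrix)
    if config.preprocessing == "msc":
        return msc(matrix)
    return savitzky_golay(
        matrix, config.sg_window, config.sg_degree, config.sg_derivative
    )


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except NircalError as exc:
        raise type(exc)(f"[stage: {name}] {exc}") from exc


def _select_and_fit(
    matrix: AbsorbanceMatrix, y: np.ndarray, config: PipelineConfig
) -> tuple[WavelengthSelection, SMLRModel]:
    labels = _stage("class split", split_classes, y, config.split_rule)
    sel = _stage(
        "anova selection", select_wavelengths, matrix, labels, config.alpha, config.cap
    )
    restricted = AbsorbanceMatrix(
        matrix.values[:, sel.selected_indices],
        matrix.wavelengths[sel.selected_indices],
        matrix.provenance + ("anova_selection",),
    )
    model = _stage(
        "stepwise regression",
        smlr_fit,
        restricted,
        y,
        config.p_enter,
        config.p_remove,
    )
    return sel, model


def _model_design(matrix: AbsorbanceMatrix, model: SMLRModel) -> np.ndarray:
    if model.n_terms == 0:
        return np.empty((matrix.n_samples, 0))
    cols = []
    for _, w, _ in model.terms:
        j = np.nonzero(np.isclose(matrix.wavelengths, w, rtol=0, atol=1e-6))[0]
        cols.append(matrix.values[:, j[0]])
    return np.column_stack(cols)


def run_pipeline(dataset: SpectraDataset, config: PipelineConfig) -> PipelineResult:
    """Run the full calibration chain and validate it."""
    y = dataset.concentrations

    band = (
        _stage(
            "cv band filter",
            lambda: remove_noisy_bands(cv_per_wavelength(dataset, config.cv_method)),
        )
        if config.cv_filter and dataset.n_acquisitions >= 2
        else None
    )

    n_avg = config.n_acquisitions or dataset.n_acquisitions
    averaged = _stage(
        "acquisition averaging",
        average_acquisitions,
        dataset,
        n_avg,
        config.seed,
        config.randomize_acquisitions,
    )
    matrix = _stage(
        "absorbance", to_absorbance, averaged.transflectance[:, 0, :], averaged.wavelengths
    )
    if band is not None:
        matrix = band.apply(matrix)
    matrix = _stage("pretreatment", _pretreat, matrix, config)

    sel, model = _select_and_fit(matrix, y, config)
    design = _model_design(matrix, model)

    if config.selection_in_fold:
        report = _nested_validation(matrix, y, config)
    elif config.validation == "loocv":
        report = _stage("loocv", loocv, design, y)
    else:
        report = _stage(
            "holdout",
            lambda: _holdout_report(design, y, config),
        )

    report.n_components_after_filter = sel.n_selected
    report.n_components_after_regression = model.n_terms
    report.preprocessing = _PREPROCESSING_LABELS[config.preprocessing]
    return PipelineResult(
        report=report,
        model=model,
        selection=sel,
        band_filter=band,
        absorbance=matrix,
        config=config,
    )


def _holdout_report(design, y, config: PipelineConfig) -> ValidationReport:
    from .validation import holdout as holdout_fn

    return holdout_fn(design, y, config.holdout_fraction, config.seed)


def _nested_validation(
    matrix: AbsorbanceMatrix, y: np.ndarray, config: PipelineConfig
) -> ValidationReport:
    """Redo ANOVA screening + stepwise selection inside every fold."""
    n = y.size
    _, full_model = _select_and_fit(matrix, y, config)
    full_design = _model_design(matrix, full_model)
    full_fit = fit_ols(full_design, y)
    calib = full_fit.intercept + full_design @ full_fit.coefficients

    if config.validation == "loocv":
        folds = [(np.flatnonzero(np.arange(n) != i), np.array([i])) for i in range(n)]
    else:
        train, valid = holdout_split(n, config.holdout_fraction, config.seed)
        folds = [(train, valid)]

    observed, predicted = [], []
    for train, valid in folds:
        sub = AbsorbanceMatrix(matrix.values[train], matrix.wavelengths, matrix.provenance)
        _, fold_model = _select_and_fit(sub, y[train], config)
        fold_design = _model_design(sub, fold_model)
        fit = fit_ols(fold_design, y[train])
        eval_design = _model_design(
            AbsorbanceMatrix(matrix.values[valid], matrix.wavelengths, matrix.provenance),
            fold_model,
        )
        predicted.append(fit.intercept + eval_design @ fit.coefficients)
        observed.append(y[valid])
    observed = np.concatenate(observed)
    predicted = np.concatenate(predicted)
    return ValidationReport(
        rmsec=rmse(y, calib),
        r2c=r2(y, calib),
        rmsev=rmse(observed, predicted),
        r2v=r2(observed, predicted),
        validation="LOOCV" if config.validation == "loocv" else "HOLDOUT",
        observed=observed,
        predicted=predicted,
    )


def _report_row(result: PipelineResult) -> dict:
    r = result.report
    return {
        "regression_algorithm": "SMLR",
        "preprocessing": r.preprocessing,
        "validation": r.validation,
        "n_components_after_filter": r.n_components_after_filter,
        "n_components_after_regression": r.n_components_after_regression,
        "rmsec_mg_kg": r.rmsec,
        "r2c": r.r2c,
        "rmsev_mg_kg": r.rmsev,
        "r2v": r.r2v,
    }


def preprocessing_table(
    dataset: SpectraDataset,
    config: PipelineConfig | None = None,
    methods: tuple[str, ...] = ("none", "snv", "msc", "sg"),
    modes: tuple[str, ...] = ("loocv", "holdout"),
) -> pd.DataFrame:
    """Results table: one row per pretreatment x validation mode."""
    config = config or PipelineConfig()
    rows = []
    for mode in modes:
        for method in methods:
            res = run_pipeline(
                dataset, config.with_(preprocessing=method, validation=mode)
            )
            rows.append(_report_row(res))
    df = pd.DataFrame(rows)
    df.attrs["config_digest"] = config_digest(config)
    return df


def sweep_sg_window(
    dataset: SpectraDataset,
    windows: tuple[int, ...] = (5, 7, 9, 11, 13, 15, 17, 19, 21),
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """RMSEC/RMSEV as a function of the SG window size.

    The returned frame carries ``attrs['best_window']``: the window with the
    lowest RMSEV, ties broken toward the smaller window.
    """
    config = (config or PipelineConfig()).with_(preprocessing="sg")
    rows = []
    for w in windows:
        res = run_pipeline(dataset, config.with_(sg_window=int(w)))
        rows.append({"window": int(w), **_report_row(res)})
    df = pd.DataFrame(rows)
    best = df.loc[df.sort_values(["rmsev_mg_kg", "window"]).index[0], "window"]
    df.attrs["best_window"] = int(best)
    df.attrs["config_digest"] = config_digest(config)
    return df


def sweep_power(
    datasets: dict[float, SpectraDataset],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """RMSEC/RMSEV per lamp-power group (one dataset per transflectance target)."""
    config = config or PipelineConfig()
    rows = []
    for target in sorted(datasets):
        res = run_pipeline(datasets[target], config)
        rows.append({"power_target_ut": float(target), **_report_row(res)})
    df = pd.DataFrame(rows)
    df.attrs["config_digest"] = config_digest(config)
    return df


def sweep_acquisitions(
    dataset: SpectraDataset,
    counts: tuple[int, ...] = tuple(range(1, 11)),
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """RMSEC/RMSEV as a function of the number of averaged acquisitions.

    The CV band filter always uses the full replicate structure; only the
    spectra entering the regression are averages of the first ``n`` captures.
    The selection and model are refit for every ``n``.
    """
    config = config or PipelineConfig()
    if max(counts) > dataset.n_acquisitions:
        raise InvalidParametersError("count exceeds the available acquisitions")
    rows = []
    for n in counts:
        res = run_pipeline(dataset, config.with_(n_acquisitions=int(n)))
        rows.append({"n_acquisitions": int(n), **_report_row(res)})
    df = pd.DataFrame(rows)
    df.attrs["config_digest"] = config_digest(config)
    return df
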