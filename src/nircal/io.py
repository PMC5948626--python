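"""Plain-text persistence for datasets, configurations and reports.

A dataset directory holds:

* ``spectra.csv`` — wide CSV, first column the sample id, second the
  acquisition id, then one column per wavelength (header = wavelength in nm);
* ``concentrations.csv`` — sample id, total polyphenols in mg/kg;
* ``groundtruth.json`` — what the generator planted (optional);
* ``config.json`` — the generator configuration (optional).

Floats are written in shortest-round-trip form, so load(save(x)) is
bitwise identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import GeneratorConfig, GroundTruth, SpectraDataset
from .errors import FormatError
from .validation import ValidationReport

__all__ = ["save_dataset", "load_dataset", "save_report", "report_table", "load_report"]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_dataset(
    dataset: SpectraDataset,
    directory,
    truth: GroundTruth | None = None,
    config: GeneratorConfig | None = None,
) -> Path:
    """Write a dataset (and optionally its ground truth/config) to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_s, n_a, _ = dataset.transflectance.shape
    flat = dataset.transflectance.reshape(n_s * n_a, -1)
    frame = pd.DataFrame(flat, columns=[repr(float(w)) for w in dataset.wavelengths])
    frame.insert(0, "acquisition", np.tile(np.arange(1, n_a + 1), n_s))
    frame.insert(0, "sample", np.repeat(np.arange(1, n_s + 1), n_a))
    frame.to_csv(directory / "spectra.csv", index=False, float_format=lambda v: repr(float(v)))
    pd.DataFrame(
        {
            "sample": np.arange(1, n_s + 1),
            "concentration_mg_kg": dataset.concentrations,
        }
    ).to_csv(directory / "concentrations.csv", index=False, float_format=lambda v: repr(float(v)))
    (directory / "metadata.json").write_text(json.dumps(_jsonable(dataset.metadata), indent=1))
    if truth is not None:
        truth_dict = _jsonable(truth)
        truth_dict.pop("noiseless_transflectance", None)  # bulky; regenerable by seed
        (directory / "groundtruth.json").write_text(json.dumps(truth_dict, indent=1))
    if config is not None:
        (directory / "config.json").write_text(json.dumps(_jsonable(config), indent=1))
    return directory


def load_dataset(directory) -> SpectraDataset:
    """Load a dataset directory written by :func:`save_dataset`."""
    directory = Path(directory)
    spath = directory / "spectra.csv"
    cpath = directory / "concentrations.csv"
    if not spath.exists() or not cpath.exists():
        raise FormatError(f"{directory} lacks spectra.csv/concentrations.csv")
    try:
        frame = pd.read_csv(spath, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {spath}: {exc}") from exc
    if frame.columns[:2].tolist() != ["sample", "acquisition"]:
        raise FormatError(
            f"{spath}: first two columns must be 'sample', 'acquisition', "
            f"got {frame.columns[:2].tolist()}"
        )
    try:
        wavelengths = np.array([float(c) for c in frame.columns[2:]])
    except ValueError as exc:
        raise FormatError(f"{spath}: non-numeric wavelength header: {exc}") from exc
    if wavelengths.size < 2 or np.any(np.diff(wavelengths) <= 0):
        raise FormatError(f"{spath}: wavelength header must be strictly increasing")
    values = frame.iloc[:, 2:]
    if not all(np.issubdtype(d, np.number) for d in values.dtypes):
        bad = [c for c, d in values.dtypes.items() if not np.issubdtype(d, np.number)]
        raise FormatError(f"{spath}: non-numeric cells in columns {bad[:3]}")
    samples = frame["sample"].to_numpy()
    acqs = frame["acquisition"].to_numpy()
    sample_ids = np.unique(samples)
    n_a = np.unique(acqs).size
    if len(frame) != sample_ids.size * n_a:
        raise FormatError(
            f"{spath}: expected a full sample x acquisition grid, "
            f"got {len(frame)} rows for {sample_ids.size} samples x {n_a} acquisitions"
        )
    order = np.lexsort((acqs, samples))
    cube = values.to_numpy()[order].reshape(sample_ids.size, n_a, wavelengths.size)

    conc = pd.read_csv(cpath, float_precision="round_trip")
    if "concentration_mg_kg" not in conc.columns:
        raise FormatError(f"{cpath}: missing 'concentration_mg_kg' column")
    conc = conc.sort_values("sample")["concentration_mg_kg"].to_numpy(dtype=float)
    if conc.size != sample_ids.size:
        raise FormatError(
            f"{cpath}: {conc.size} concentrations for {sample_ids.size} samples"
        )
    metadata = {}
    mpath = directory / "metadata.json"
    if mpath.exists():
        metadata = json.loads(mpath.read_text())
    return SpectraDataset(
        transflectance=cube,
        wavelengths=wavelengths,
        concentrations=conc,
        metadata=metadata,
    )


def save_report(report: ValidationReport, path) -> Path:
    """Serialize a single validation report to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "rmsec_mg_kg": report.rmsec,
        "r2c": report.r2c,
        "rmsev_mg_kg": report.rmsev,
        "r2v": report.r2v,
        "n_components_after_filter": report.n_components_after_filter,
        "n_components_after_regression": report.n_components_after_regression,
        "preprocessing": report.preprocessing,
        "validation": report.validation,
        "pairs": [
            [float(o), float(p)] for o, p in zip(report.observed, report.predicted)
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_report(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no report at {path}")
    return json.loads(path.read_text())


def report_table(reports, path=None) -> pd.DataFrame:
    """Stack reports into the standard results table (one row each); write a
    CSV alongside if ``path`` is given."""
    rows = []
    for r in reports:
        rows.append(
            {
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
        )
    df = pd.DataFrame(rows)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
    return df
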