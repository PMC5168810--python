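"""Readers and writers for the TSV/CSV interchange formats.

The matrix format follows GEO series-matrix habits: row 1 holds the
sample IDs, column 1 the feature IDs, tab- or comma-separated by file
extension.  Labels come either from a two-column file (sample_id,
condition) or a ``A=s1,s2 B=s3,s4`` assignment string.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import ExpressionDataset
from .discriminant_cut import DetectionResult

__all__ = [
    "read_matrix",
    "read_labels",
    "parse_group_string",
    "scale_round",
    "load_dataset",
    "write_matrix",
    "write_results",
    "write_report",
]


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample matrix with IDs; rejects duplicates and gaps."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate feature ID: {dup}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"missing value at feature {row}, sample {col}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return values


def write_matrix(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_delimiter(path))


def read_labels(path) -> pd.Series:
    """Two-column (sample_id, condition) label file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path), header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: sample_id, condition")
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def parse_group_string(spec: str) -> pd.Series:
    """Parse ``A=s1,s2 B=s3,s4`` into a sample -> condition mapping."""
    mapping = {}
    for part in spec.split():
        if "=" not in part:
            raise ValueError(f"bad group spec fragment: {part!r}")
        name, samples = part.split("=", 1)
        for s in samples.split(","):
            if s:
                mapping[s] = name
    if len(set(mapping.values())) != 2:
        raise ValueError("group spec must define exactly two conditions")
    return pd.Series(mapping)


def scale_round(values: np.ndarray, factor: float) -> np.ndarray:
    """round(values * factor) elementwise, half away from zero.

    Continuous measurements (e.g. methylation fractions) become integer
    pseudo-counts acceptable to the count-based extractors.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    x = np.asarray(values, dtype=float) * factor
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def load_dataset(matrix_path, labels: pd.Series, scale_round_factor: float | None = None):
    """Assemble an ExpressionDataset from a matrix file and a label map."""
    df = read_matrix(matrix_path)
    missing = [s for s in df.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    values = df.values
    if scale_round_factor is not None:
        values = scale_round(values, scale_round_factor)
    return ExpressionDataset(
        values=values,
        feature_ids=list(df.index),
        sample_ids=list(df.columns),
        labels=labels.loc[df.columns].values,
    )


def write_results(result: DetectionResult, stats, attribute_names, out_path) -> None:
    """Per-feature results TSV plus a JSON sidecar with run provenance."""
    out_path = Path(out_path)
    table = pd.DataFrame(stats, index=result.feature_ids, columns=attribute_names)
    table.index.name = "feature_id"
    for direction in ("up", "down"):
        if direction in result.fits:
            table[f"d_{direction}"] = result.fits[direction].d_values
    table["called"] = result.calls
    table.to_csv(out_path, sep="\t")

    sidecar = {"version": __version__, "n_called": result.n_called, "models": {}}
    if result.config is not None:
        sidecar["config"] = asdict(result.config)
    sidecar["effective_B"] = result.effective_B
    for direction, fit in result.fits.items():
        entry = {"status": fit.status, "n_grid": fit.n_grid}
        if fit.model is not None:
            entry["weights"] = fit.model.weights.tolist()
            entry["tau"] = fit.model.tau
        for phase in ("search", "calibrated"):
            est = getattr(fit, f"fdr_{phase}")
            if est is not None:
                entry[f"fdr_{phase}"] = asdict(est)
        sidecar["models"][direction] = entry
    with open(out_path.with_suffix(out_path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, default=float)


def write_report(report: dict, out_path) -> None:
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)
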