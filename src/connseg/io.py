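"""File I/O: every pipeline artifact as inspectable delimited text.

Conventions: tab-separated UTF-8 with a header row; matrices carry node
labels as both header and first column; numeric values are serialized with
full ``repr`` precision so write-then-read round-trips are exact.  Run
outputs are accompanied by a JSON sidecar recording the seed and a hash of
the configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def write_timeseries(path, ts: np.ndarray, labels) -> None:
    """One scan: rows = ROIs (first column the label), columns = time points."""
    ts = np.asarray(ts, dtype=float)
    if len(labels) != ts.shape[0]:
        raise ValueError("label count does not match ROI count")
    df = pd.DataFrame(ts, index=pd.Index(labels, name="label"))
    df.columns = [f"t{c}" for c in df.columns]
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_timeseries(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.empty or df.shape[1] < 1:
        raise ValueError(f"malformed time-series file: {path}")
    return df.to_numpy(dtype=float), df.index.tolist()


def write_matrix(path, matrix: np.ndarray, labels) -> None:
    """Square matrix with node labels as header row and index column."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or len(labels) != n:
        raise ValueError("matrix must be square with one label per node")
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.index.name = "label"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"matrix file {path} is not square: {df.shape[0]}x{df.shape[1]}"
        )
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix file {path}: row and column labels differ")
    return df.to_numpy(dtype=float), df.index.tolist()


COVARIATE_COLUMNS = [
    "subject_id", "cohort", "arm", "timepoint", "age", "gender",
    "education", "severity", "motion_rms", "behavior_gain",
]


def write_covariates(path, covariates: pd.DataFrame) -> None:
    missing = set(COVARIATE_COLUMNS) - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table missing column(s): {sorted(missing)}")
    covariates[COVARIATE_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"covariate file {path} missing column(s): {sorted(missing)}"
        )
    ppa = df[df["cohort"] == "PPA"]
    if ppa["severity"].isna().any():
        bad = ppa.loc[ppa["severity"].isna(), "subject_id"].tolist()
        raise ValueError(f"severity missing for patient row(s): {bad}")
    return df


def write_node_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_node_table(path) -> pd.DataFrame:
    from connseg.nodes import validate_node_table

    table = pd.read_csv(path, sep="\t")
    validate_node_table(table)
    return table


def write_metrics(path, metrics: pd.DataFrame) -> None:
    metrics.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"threshold": str, "timepoint": str}
    )


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
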