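"""Reading and writing measurement tables, coefficient files and fit reports.

The measurement CSV dialect is fixed: comma separator, dot decimal, UTF-8,
header exactly ``test_id,ca_mM,cb_mM,ph,ef_nA``, no index column.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CoefficientVector

__all__ = [
    "MEASUREMENT_COLUMNS",
    "SchemaError",
    "read_measurement_csv",
    "write_measurement_csv",
    "load_measured_runs",
    "load_predicted_runs",
    "write_coefficients_json",
    "read_coefficients_json",
    "write_fit_report",
    "read_fit_report",
]

MEASUREMENT_COLUMNS = ("test_id", "ca_mM", "cb_mM", "ph", "ef_nA")


class SchemaError(ValueError):
    """The CSV header or types do not match the measurement schema."""


def read_measurement_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement table; row order preserved."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")
    extra = [c for c in df.columns if c not in MEASUREMENT_COLUMNS]
    if extra:
        raise SchemaError(f"unexpected column(s) {extra} in {path}")
    if len(df) == 0:
        raise SchemaError(f"no data rows in {path}")
    for col in ("ca_mM", "cb_mM", "ph", "ef_nA"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric value in column {col!r} at data row {int(bad[0]) + 1}"
            )
        df[col] = vals.astype(float)
    df["test_id"] = df["test_id"].astype(int)
    if df["test_id"].duplicated().any():
        dup = int(df["test_id"][df["test_id"].duplicated()].iloc[0])
        raise SchemaError(f"duplicate test_id {dup}")
    for col, ok, msg in (
        ("ca_mM", df["ca_mM"] >= 0, "urea concentration must be >= 0"),
        ("cb_mM", df["cb_mM"] > 0, "buffer concentration must be > 0"),
        ("ph", df["ph"] > 0, "pH must be > 0"),
        ("ef_nA", np.isfinite(df["ef_nA"]), "current must be finite"),
    ):
        bad = df.index[~ok]
        if len(bad):
            raise SchemaError(f"{msg} (data row {int(bad[0]) + 1})")
    return df[list(MEASUREMENT_COLUMNS)]


def write_measurement_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[list(MEASUREMENT_COLUMNS)].to_csv(path, index=False)


def _bundled(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("ureafit.data") / name) as p:
        return read_measurement_csv(p)


def load_measured_runs() -> pd.DataFrame:
    """The 9 measured calibration runs (L9 design, currents in nA)."""
    return _bundled("table1.csv")


def load_predicted_runs() -> pd.DataFrame:
    """The 18 externally predicted runs (test ids 10-27).

    Reference data only: their generating procedure is unpublished and this
    package does not attempt to reproduce the values.
    """
    return _bundled("table2.csv")


def write_coefficients_json(coeffs: CoefficientVector, path: str | Path) -> None:
    payload = coeffs.to_dict()
    payload["units"] = "nA"
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_coefficients_json(path: str | Path) -> CoefficientVector:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return CoefficientVector.from_dict(payload)


def write_fit_report(result, path: str | Path) -> None:
    """Serialize a FitResult (coefficients at full float precision)."""
    Path(path).write_text(
        json.dumps(result.to_dict(), indent=2) + "\n", encoding="utf-8"
    )


def read_fit_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
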