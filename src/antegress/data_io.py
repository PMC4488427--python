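"""Reading and writing egress event tables.

The canonical on-disk format is a tidy delimited table with one row per
escape event and columns::

    trial_id, condition, exit_width_cm, n_initial, egress_time_s

``n_initial`` is optional on input (default 30, the design's nominal count).
Input times may be absolute clock times; each trial is re-referenced so its
earliest escape is time zero. Spreadsheet (XLSX) import is supported for
deposited raw-data files, but because such sheets have no fixed layout the
caller must supply an explicit column mapping rather than letting the reader
guess.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ParseError
from .types import EgressSeries, ExperimentDataset, normalize_condition

REQUIRED_COLUMNS = ("trial_id", "condition", "exit_width_cm", "egress_time_s")
CANONICAL_COLUMNS = ("trial_id", "condition", "exit_width_cm", "n_initial", "egress_time_s")

_DEFAULT_N_INITIAL = 30

_DIALECTS = {".csv": "csv", ".tsv": "tsv", ".xlsx": "xlsx"}


def _infer_dialect(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _DIALECTS:
        raise ConfigurationError(
            f"cannot infer dialect from {path!r}; pass dialect='csv'|'tsv'|'xlsx'"
        )
    return _DIALECTS[ext]


def _numeric_column(df: pd.DataFrame, column: str) -> np.ndarray:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {df[column].iloc[row]!r} in column {column!r} at row {row}"
        )
    if values.isna().any():
        row = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise ParseError(f"missing value in column {column!r} at row {row}")
    return values.to_numpy(dtype=float)


def read_egress_table(
    path,
    dialect: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
    sheet=0,
) -> ExperimentDataset:
    """Read an event table into an :class:`ExperimentDataset`.

    Parameters
    ----------
    path
        CSV, TSV, or XLSX file.
    dialect
        ``"csv"``, ``"tsv"``, or ``"xlsx"``; inferred from the file suffix
        when omitted.
    column_map
        Mapping from canonical column names to the names used in the file.
        Required for XLSX input; optional for delimited input.
    sheet
        Sheet name or index for XLSX input (first sheet by default).

    Times within each trial are sorted and shifted so the earliest escape is
    at 0 s; row order in the file is irrelevant.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif dialect == "xlsx":
        if column_map is None:
            raise ConfigurationError(
                "XLSX import requires an explicit column_map "
                "(canonical name -> sheet column name)"
            )
        df = pd.read_excel(path, sheet_name=sheet, engine="openpyxl")
    else:
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        missing_src = [src for src in rename if src not in df.columns]
        if missing_src:
            raise FormatError(f"mapped column(s) not found in file: {missing_src}")
        df = df.rename(columns=rename)

    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} is missing")

    times = _numeric_column(df, "egress_time_s")
    widths = _numeric_column(df, "exit_width_cm")
    if "n_initial" in df.columns:
        n_initial = _numeric_column(df, "n_initial").astype(int)
    else:
        n_initial = np.full(len(df), _DEFAULT_N_INITIAL, dtype=int)
    conditions = [normalize_condition(c) for c in df["condition"]]

    work = pd.DataFrame(
        {
            "trial_id": df["trial_id"].astype(str),
            "condition": conditions,
            "exit_width_cm": widths,
            "n_initial": n_initial,
            "egress_time_s": times,
        }
    )

    series = []
    for trial_id, grp in work.groupby("trial_id", sort=True):
        for col in ("condition", "exit_width_cm", "n_initial"):
            if grp[col].nunique() > 1:
                raise FormatError(
                    f"trial {trial_id!r} has inconsistent {col!r} values: "
                    f"{sorted(grp[col].unique())}"
                )
        t = np.sort(grp["egress_time_s"].to_numpy())
        t = t - t[0]  # time-zero convention
        series.append(
            EgressSeries(
                trial_id=str(trial_id),
                condition=grp["condition"].iloc[0],
                exit_width_cm=float(grp["exit_width_cm"].iloc[0]),
                n_initial=int(grp["n_initial"].iloc[0]),
                times_s=t,
            )
        )
    return ExperimentDataset(series=tuple(series), provenance=str(path))


def write_egress_table(dataset: ExperimentDataset, path) -> None:
    """Write a dataset to the canonical CSV format (one row per event).

    An empty dataset produces a header-only file. Times round-trip to at
    least 6 significant digits (12 are written).
    """
    rows = []
    for s in dataset:
        for t in s.times_s:
            rows.append((s.trial_id, s.condition, s.exit_width_cm, s.n_initial, t))
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")
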