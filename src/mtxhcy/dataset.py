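"""NONMEM-style rectangular dataset I/O.

One row per event: dose rows carry ``EVID=1, MDV=1, AMT>0``; observation
rows carry ``EVID=0, AMT=0`` and the measured concentration in ``DV``
(µM), with missing values written as ``"."``.  ``DVID`` labels the analyte
("MTX"/"HCY") on observation rows and the administered drug ("MTX"/"FOL")
on dose rows.  ``TIME`` is hours from the start of the course indexed by
``OCC``.  Covariates are repeated on every row of a subject.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "read_dataset", "write_dataset", "validate_dataset"]

COLUMNS = [
    "ID", "OCC", "TIME", "AMT", "RATE", "CMT", "EVID", "MDV", "DV", "DVID",
    "AGE", "SEX", "BSA", "WT", "HT", "SCR", "RISK",
]

_INT_COLS = ["ID", "OCC", "CMT", "EVID", "MDV"]
_FLOAT_COLS = ["TIME", "AMT", "RATE", "DV", "AGE", "BSA", "WT", "HT", "SCR"]
_STR_COLS = ["DVID", "SEX", "RISK"]

#: compartment codes
CMT_MTX = 1
CMT_HCY = 2
CMT_FOLINATE = 3


class DatasetError(ValueError):
    """A structural problem in a rectangular dataset."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants; returns the frame sorted by ID/OCC/TIME."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"dataset is missing required column(s): {missing}")
    if (df["TIME"] < 0).any():
        raise DatasetError("negative TIME values present")
    doses = df["EVID"] == 1
    if (df.loc[doses, "MDV"] != 1).any():
        raise DatasetError("dose rows must have MDV=1")
    if df.loc[doses, "DV"].notna().any():
        raise DatasetError("dose rows must not carry a DV")
    obs = df["EVID"] == 0
    if (df.loc[obs, "AMT"].fillna(0) != 0).any():
        raise DatasetError("observation rows must have AMT=0")
    out = df.sort_values(["ID", "OCC", "TIME", "EVID"], kind="stable").reset_index(drop=True)
    return out


def write_dataset(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset CSV with a mandatory header; missing DV coded '.'."""
    df = validate_dataset(rows.copy())
    df = df[COLUMNS]
    out = df.copy()
    out["DV"] = out["DV"].map(lambda v: "." if pd.isna(v) else format(float(v), ".10g"))
    out.to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a dataset CSV; lossless round-trip partner of :func:`write_dataset`."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"dataset file is missing required column(s): {missing}")
    df = df[COLUMNS].copy()
    df["DV"] = df["DV"].replace({".": np.nan, "": np.nan})
    for c in _INT_COLS:
        df[c] = df[c].astype(int)
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    for c in _STR_COLS:
        df[c] = df[c].astype(str)
    return validate_dataset(df)
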