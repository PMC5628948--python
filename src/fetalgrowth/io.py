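"""Format-stable CSV readers/writers for cohort scans and delivery outcomes.

Schemas (header required, UTF-8, '.' decimal separator, empty field = missing):

scans:    subject_id, ga_days, bpd_mm, hc_mm, ac_mm, fl_mm, tvol_cm3, thigh_circ_mm
outcomes: subject_id, birthweight_g, ga_delivery_days, sex, maternal_height_cm,
          maternal_weight_kg, parity, ethnicity

Malformed rows are reported with their line numbers, never silently dropped.
"""

from __future__ import annotations

import os

import pandas as pd

from .biometry import BiometryScan
from .errors import FormatError

__all__ = [
    "SCAN_COLUMNS",
    "OUTCOME_COLUMNS",
    "read_cohort_csv",
    "read_outcomes_csv",
    "write_cohort_csv",
    "write_outcomes_csv",
]

SCAN_COLUMNS = ("subject_id", "ga_days", "bpd_mm", "hc_mm", "ac_mm", "fl_mm",
                "tvol_cm3", "thigh_circ_mm")
OUTCOME_COLUMNS = ("subject_id", "birthweight_g", "ga_delivery_days", "sex",
                   "maternal_height_cm", "maternal_weight_kg", "parity", "ethnicity")


def _read_validated(path: str, columns: tuple[str, ...]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"input file not found: {path}")
    if os.path.getsize(path) == 0:
        raise FormatError(f"{path}: file is empty (a header is required)")
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    unknown = set(df.columns) - set(columns)
    if missing or unknown:
        raise FormatError(
            f"{path}: schema mismatch — missing columns {sorted(missing)}, "
            f"unknown columns {sorted(unknown)}"
        )
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    return df[list(columns)]


def read_cohort_csv(path: str) -> pd.DataFrame:
    """Read and validate a long-format scan file (one row per scan)."""
    df = _read_validated(path, SCAN_COLUMNS)
    errors = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            BiometryScan(
                subject_id=str(row["subject_id"]),
                ga_days=int(row["ga_days"]),
                **{c: (None if pd.isna(row[c]) else float(row[c]))
                   for c in SCAN_COLUMNS[2:]},
            )
        except Exception as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise FormatError(
            f"{path}: {len(errors)} invalid scan row(s):\n  " + "\n  ".join(errors[:20])
        )
    return df


def read_outcomes_csv(path: str) -> pd.DataFrame:
    """Read and validate the delivery-outcomes file (one row per subject)."""
    df = _read_validated(path, OUTCOME_COLUMNS)
    errors = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            bw = float(row["birthweight_g"])
            ga = float(row["ga_delivery_days"])
            if not (bw > 0):
                raise ValueError(f"birthweight_g={bw} must be > 0")
            if not (140 <= ga <= 310):
                raise ValueError(f"ga_delivery_days={ga} implausible")
            if str(row["sex"]) not in ("male", "female"):
                raise ValueError(f"sex={row['sex']!r} must be male/female")
            if int(row["parity"]) < 0:
                raise ValueError("parity must be >= 0")
        except Exception as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise FormatError(
            f"{path}: {len(errors)} invalid outcome row(s):\n  " + "\n  ".join(errors[:20])
        )
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise FormatError(f"{path}: duplicated subject_id(s): {dupes[:10]}")
    return df


def write_cohort_csv(path: str, scans: pd.DataFrame) -> None:
    scans[list(SCAN_COLUMNS)].to_csv(path, index=False)


def write_outcomes_csv(path: str, outcomes: pd.DataFrame) -> None:
    outcomes[list(OUTCOME_COLUMNS)].to_csv(path, index=False)
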