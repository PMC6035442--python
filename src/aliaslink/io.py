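"""Schema-validated CSV readers and writers shared by all pipeline stages.

Partial dates travel as separate day/month/year columns; a missing day
or month is an empty field in the file and a nullable-integer NA in
memory (never a sentinel value). Errors name the offending column or
row so a malformed hand-edited file fails with a usable diagnostic.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .evaluation import DataError
from .synthetic import COHORT_COLUMNS, REGISTRY_COLUMNS, TRUTH_COLUMNS

__all__ = [
    "read_cohort",
    "read_registry",
    "read_truth",
    "read_links",
    "write_links",
    "LINK_COLUMNS",
]

LINK_COLUMNS = [
    "person_id", "death_id", "max_weight", "contributing_statuses",
    "classification", "duplicate_flag", "conflict_flag",
]

_DOB_COLS = ("dob_day", "dob_month", "dob_year")


def _read(path: str | Path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise DataError(f"cannot read {label} file {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{label} file {path} lacks column(s) {missing}")
    return df


def _parse_dob(df: pd.DataFrame, label: str) -> pd.DataFrame:
    for col in _DOB_COLS:
        if col not in df.columns:
            continue
        raw = df[col].replace("", pd.NA)
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & parsed.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise DataError(f"{label}: malformed {col} at line {row}")
        df[col] = parsed.astype("Int64")
    return df


def _check_dates(df: pd.DataFrame, col: str, label: str) -> None:
    parsed = pd.to_datetime(df[col].replace("", pd.NA), errors="coerce",
                            format="%Y-%m-%d")
    bad = df[col].ne("").to_numpy() & parsed.isna().to_numpy()
    if bad.any():
        row = int(bad.argmax()) + 2
        raise DataError(f"{label}: malformed {col} at line {row}")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read an identity-record file; record_id must be unique."""
    df = _read(path, COHORT_COLUMNS, "cohort")
    df = _parse_dob(df, "cohort")
    _check_dates(df, "last_contact_date", "cohort")
    if df["record_id"].duplicated().any():
        dup = df.loc[df["record_id"].duplicated(), "record_id"].iloc[0]
        raise DataError(f"cohort: duplicate record_id {dup!r}")
    bad_status = ~df["record_status"].isin(["birth", "legal", "alias"])
    if bad_status.any():
        row = int(bad_status.to_numpy().argmax()) + 2
        raise DataError(f"cohort: unknown record_status at line {row}")
    return df


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read a death-registry file; day and month of birth may be blank."""
    df = _read(path, REGISTRY_COLUMNS, "registry")
    df = _parse_dob(df, "registry")
    _check_dates(df, "death_date", "registry")
    if df["death_id"].duplicated().any():
        dup = df.loc[df["death_id"].duplicated(), "death_id"].iloc[0]
        raise DataError(f"registry: duplicate death_id {dup!r}")
    # day and month of birth are jointly present or jointly missing
    if len(df):
        day_na = df["dob_day"].isna()
        month_na = df["dob_month"].isna()
        odd = day_na != month_na
        if odd.any():
            row = int(odd.to_numpy().argmax()) + 2
            raise DataError(
                f"registry: dob_day and dob_month must be jointly missing "
                f"(line {row})"
            )
    return df


def read_truth(path: str | Path) -> pd.DataFrame:
    return _read(path, TRUTH_COLUMNS, "truth")


def read_links(path: str | Path) -> pd.DataFrame:
    df = _read(path, ["person_id", "death_id", "contributing_statuses"], "links")
    if "max_weight" in df.columns:
        df["max_weight"] = pd.to_numeric(df["max_weight"], errors="coerce")
    for col in ("duplicate_flag", "conflict_flag", "anomaly_flag"):
        if col in df.columns:
            df[col] = df[col].isin(["True", "true", "1"])
    return df


def write_links(links: pd.DataFrame, path: str | Path) -> Path:
    """Write a person-link table with the documented column order."""
    path = Path(path)
    out = links.copy()
    for col in LINK_COLUMNS:
        if col not in out.columns:
            out[col] = "" if col == "classification" else pd.NA
    extra = [c for c in out.columns if c not in LINK_COLUMNS]
    out[LINK_COLUMNS + extra].to_csv(path, index=False)
    return path
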