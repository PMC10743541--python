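"""Cohort table I/O.

The cohort TSV dialect has a fixed header and column order (see
:data:`COHORT_COLUMNS`): tab-separated, one row per subject, booleans written
as ``true``/``false``, missing values as empty fields (``NA`` is also
accepted on read).  Floats are written with ``repr`` precision so a
write/read round trip reproduces the records exactly.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

FLOAT_COLUMNS: tuple[str, ...] = (
    "age_baseline",
    "cer_16_0", "cer_18_0", "cer_24_0", "cer_24_1",
    "pc_14_0_22_6", "pc_16_0_22_5", "pc_16_0_16_0",
    "bmi", "waist", "tg", "tc", "hdl", "ldl", "crp",
    "sbp", "dbp", "age_at_event_or_censor",
)
BOOL_COLUMNS: tuple[str, ...] = (
    "smoking", "diabetes", "lipid_lowering_tx", "bp_lowering_tx",
    "prevalent_htn", "event_new_onset", "died",
)
STR_COLUMNS: tuple[str, ...] = ("subject_id", "sex")

#: Fixed column order of the cohort TSV dialect.
COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id", "age_baseline", "sex",
    "cer_16_0", "cer_18_0", "cer_24_0", "cer_24_1",
    "pc_14_0_22_6", "pc_16_0_22_5", "pc_16_0_16_0",
    "bmi", "waist", "tg", "tc", "hdl", "ldl", "crp",
    "smoking", "diabetes", "lipid_lowering_tx", "bp_lowering_tx",
    "sbp", "dbp", "prevalent_htn",
    "event_new_onset", "age_at_event_or_censor", "died",
)

_MISSING_TOKENS = {"", "NA"}


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort to TSV in the documented dialect and column order."""
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort is missing columns: {missing}")

    def fmt(col: str, v) -> str:
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
            return ""
        if col in BOOL_COLUMNS:
            return "true" if bool(v) else "false"
        if col in FLOAT_COLUMNS:
            return repr(float(v))
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(COHORT_COLUMNS) + "\n")
        cols = [cohort[c].tolist() for c in COHORT_COLUMNS]
        for row in zip(*cols):
            fh.write("\t".join(fmt(c, v) for c, v in zip(COHORT_COLUMNS, row)) + "\n")


def _parse_cell(col: str, raw: str, line_no: int):
    if raw in _MISSING_TOKENS:
        return None
    if col in FLOAT_COLUMNS:
        try:
            return float(raw)
        except ValueError:
            raise DataError(
                f"line {line_no}: non-numeric value {raw!r} in column {col!r}"
            ) from None
    if col in BOOL_COLUMNS:
        low = raw.lower()
        if low in ("true", "1"):
            return True
        if low in ("false", "0"):
            return False
        raise DataError(f"line {line_no}: non-boolean value {raw!r} in column {col!r}")
    return raw


def read_cohort(
    path,
    column_map: Mapping[str, str] | None = None,
    on_bad_row: str = "error",
) -> pd.DataFrame:
    """Read a cohort TSV (or any delimited file via ``column_map``).

    ``column_map`` maps file column names to canonical cohort names.  Rows
    with malformed typed values raise :class:`DataError` with the line
    number, or are skipped with a logged count under ``on_bad_row="skip"``.
    """
    if on_bad_row not in ("error", "skip"):
        raise SchemaError(f"on_bad_row must be 'error' or 'skip', got {on_bad_row!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if column_map:
            header = [column_map.get(h, h) for h in header]
        missing = [c for c in COHORT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"cohort file {path} is missing column(s): {missing}")
        idx = {c: header.index(c) for c in COHORT_COLUMNS}

        records: dict[str, list] = {c: [] for c in COHORT_COLUMNS}
        n_skipped = 0
        for line_no, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                if on_bad_row == "skip":
                    n_skipped += 1
                    continue
                raise DataError(f"line {line_no}: expected {len(header)} fields")
            try:
                parsed = {c: _parse_cell(c, fields[idx[c]], line_no) for c in COHORT_COLUMNS}
            except DataError:
                if on_bad_row == "skip":
                    n_skipped += 1
                    continue
                raise
            for c, v in parsed.items():
                records[c].append(v)

    df = pd.DataFrame(records)
    for c in FLOAT_COLUMNS:
        df[c] = df[c].astype(float)
    for c in BOOL_COLUMNS:
        df[c] = df[c].astype(object).where(df[c].notna(), np.nan)
        if df[c].notna().all():
            df[c] = df[c].astype(bool)
    n = len(df)
    logger.info("read_cohort(%s): %d row(s), %d skipped", path, n, n_skipped)
    df.attrs["n_skipped"] = n_skipped
    return df
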