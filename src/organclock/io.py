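"""TSV readers/writers for the pipeline's tables.

All tables travel as tab-separated text with a header row; dates are
ISO-8601.  Genotypes travel as a dosage TSV (rows = participants,
columns = variant ids) or a minimal VCF with a DS field (see
:mod:`organclock.scores`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_participants",
    "read_participants",
    "write_records",
    "read_records",
    "write_table",
    "read_table",
]

_DATE_COLUMNS = ("recruitment_date", "date_of_birth", "first_event_date")


def write_participants(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=True, date_format="%Y-%m-%d")


def read_participants(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    for col in _DATE_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_datetime(table[col])
    return table


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, date_format="%Y-%m-%d")


def read_records(path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t")
    records["event_date"] = pd.to_datetime(records["event_date"])
    return records


def write_table(table: pd.DataFrame, path, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index, date_format="%Y-%m-%d")


def read_table(path, index_col=0) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=index_col)
    for col in _DATE_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_datetime(table[col])
    return table


def ensure_dir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out
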