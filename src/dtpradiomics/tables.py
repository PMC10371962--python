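"""Lesion feature tables.

A feature table is a pandas DataFrame with four mandatory metadata columns
(``lesion_id``, ``patient_id``, ``center_id``, ``outcome``) followed by
feature columns in a stable, documented order.  ``outcome`` is binary:
1 = responding, 0 = non-responding (the coding is configurable downstream).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

META_COLUMNS = ["lesion_id", "patient_id", "center_id", "outcome"]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature column names in stored order (everything after the metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing mandatory column(s): {missing}")
    if table["lesion_id"].duplicated().any():
        dups = table.loc[table["lesion_id"].duplicated(), "lesion_id"].tolist()
        raise ValueError(f"duplicate lesion_id values: {dups}")
    if table[["center_id", "outcome"]].isna().any().any():
        raise ValueError("center_id and outcome must be non-empty for every lesion")
    return table


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a lesion feature table from CSV (comma, UTF-8, '.' decimal)."""
    table = pd.read_csv(path, dtype={c: str for c in META_COLUMNS if c != "outcome"})
    return validate_feature_table(table)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_feature_table(table)
    cols = META_COLUMNS + feature_columns(table)
    table[cols].to_csv(path, index=False)
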