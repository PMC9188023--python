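"""CSV interchange for parameter and trait tables.

Comma-separated, UTF-8, decimal point; column names carry units.  The
parameter schema mirrors the naming of curated DEB parameter collections.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .deb_core import DEBParameters, InvalidParameterError
from .traits import TRAIT_COLUMNS

__all__ = [
    "PARAMETER_COLUMNS",
    "OPTIONAL_PARAMETER_COLUMNS",
    "read_parameter_table",
    "write_parameter_table",
    "read_trait_table",
    "write_trait_table",
]

#: required columns of a parameter CSV, in order, mapped to field names
PARAMETER_COLUMNS = {
    "species_id": "species_id",
    "taxon": "taxon",
    "T_A_K": "T_A",
    "p_Am_J_d_cm2": "p_Am",
    "v_cm_d": "v",
    "kappa": "kappa",
    "kappa_R": "kappa_R",
    "p_M_J_d_cm3": "p_M",
    "k_J_1_d": "k_J",
    "E_G_J_cm3": "E_G",
    "E_Hb_J": "E_Hb",
    "E_Hp_J": "E_Hp",
    "h_a_1_d2": "h_a",
    "s_G": "s_G",
}

OPTIONAL_PARAMETER_COLUMNS = {"sub_taxon": "sub_taxon", "f": "f"}

_NUMERIC = [c for c in PARAMETER_COLUMNS if c not in ("species_id", "taxon")]


def read_parameter_table(path: str | Path) -> list[DEBParameters]:
    """Read and validate a parameter CSV into typed records.

    Raises with the offending column name if a required column is absent,
    and with the row index (0-based data row) and column for non-numeric
    or out-of-range values.
    """
    frame = pd.read_csv(path)
    missing = [c for c in PARAMETER_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column: {', '.join(missing)}")
    for col in _NUMERIC + [c for c in ("f",) if c in frame.columns]:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col}: {exc}") from exc

    records = []
    for idx, row in frame.iterrows():
        kwargs = {field: row[col] for col, field in PARAMETER_COLUMNS.items()}
        for col, field in OPTIONAL_PARAMETER_COLUMNS.items():
            if col in frame.columns and not pd.isna(row[col]):
                kwargs[field] = row[col]
        kwargs["species_id"] = str(kwargs["species_id"])
        kwargs["taxon"] = "" if pd.isna(kwargs["taxon"]) else str(kwargs["taxon"])
        if "sub_taxon" in kwargs:
            kwargs["sub_taxon"] = str(kwargs["sub_taxon"])
        try:
            records.append(DEBParameters(**kwargs))
        except InvalidParameterError as exc:
            raise ValueError(f"row {idx}: {exc}") from exc
    return records


def write_parameter_table(params: Iterable[DEBParameters], path: str | Path) -> None:
    """Write parameter records to CSV in the documented schema."""
    rows = []
    for p in params:
        row = {col: getattr(p, field) for col, field in PARAMETER_COLUMNS.items()}
        row["sub_taxon"] = p.sub_taxon
        row["f"] = p.f
        rows.append(row)
    cols = list(PARAMETER_COLUMNS) + list(OPTIONAL_PARAMETER_COLUMNS)
    pd.DataFrame(rows).reindex(columns=cols).to_csv(path, index=False)


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trait table to CSV; missing values as empty fields."""
    table.reindex(columns=TRAIT_COLUMNS).to_csv(path, index=False)


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a trait table written by :func:`write_trait_table`."""
    table = pd.read_csv(path)
    for col in ("species_id", "taxon", "sub_taxon"):
        if col in table.columns:
            table[col] = table[col].fillna("").astype(str)
    for flag in ("non_viable", "stalled", "demand_bound"):
        if flag in table.columns:
            table[flag] = table[flag].astype(bool)
    return table
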