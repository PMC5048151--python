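"""Schema and I/O for specimen measurement tables.

A measurement table is a :class:`pandas.DataFrame` with one row per
specimen, an identifier column ``specimen_id``, a group column
``species`` and 25 strictly positive linear characters named by the
standard abbreviations in :data:`CHARACTERS`.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: The 25 linear characters, in canonical column order.
CHARACTERS: tuple[str, ...] = (
    "CL", "CW",
    "F1L", "F1W", "F2L", "F2W", "F3L", "F3W",
    "F4L", "F4W", "F5L", "F5W", "F6L", "F6W",
    "FT", "HT", "MT", "MTS",
    "OV", "PL", "PVL", "PW",
    "SL", "SVL", "SW",
)

ID_COLUMNS = ("specimen_id", "species")


def validate_measurement_table(table: pd.DataFrame, *, require_positive: bool = True) -> pd.DataFrame:
    """Check column schema and positivity; return the table unchanged.

    Raises
    ------
    SchemaError
        If an id column or character column is missing, or the table
        carries an unknown measurement column.
    ValidationError
        If ``require_positive`` and any measurement is not > 0.
    """
    missing = [c for c in (*ID_COLUMNS, *CHARACTERS) if c not in table.columns]
    if missing:
        raise SchemaError(f"measurement table is missing columns: {missing}")
    unknown = [c for c in table.columns if c not in (*ID_COLUMNS, *CHARACTERS)]
    if unknown:
        raise SchemaError(f"measurement table has unknown columns: {unknown}")
    if table["specimen_id"].duplicated().any():
        dups = table.loc[table["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValidationError(f"duplicate specimen ids: {dups}")
    if require_positive:
        values = table[list(CHARACTERS)].to_numpy(dtype=float)
        bad = ~(np.isnan(values) | (values > 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive measurement for specimen "
                f"{table['specimen_id'].iloc[i]!r}, character {CHARACTERS[j]!r}"
            )
    return table


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement table from CSV and validate its schema."""
    return validate_measurement_table(pd.read_csv(path))


def write_measurements(table: pd.DataFrame, path) -> None:
    """Write a measurement table to CSV in canonical column order."""
    validate_measurement_table(table)
    table[[*ID_COLUMNS, *CHARACTERS]].to_csv(path, index=False)
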