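"""Cell-table TSV I/O.

The unit of analysis downstream of segmentation is a cell table: one row per
segmented cell with its centroid (micrometers), sample/ROI id, experimental
condition, one column of total intensity per marker, and optional cluster /
annotation columns appended by later stages.  Tables are exchanged as
tab-separated UTF-8 text with Unix newlines.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import FormatError

MANDATORY_COLUMNS = ["cell_id", "x_um", "y_um", "sample_id", "condition"]

#: non-marker columns that may legitimately appear in a cell table
RESERVED_COLUMNS = MANDATORY_COLUMNS + ["area_px", "cluster", "annotation", "phenotype"]


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"cell table missing mandatory column {col!r}")
    return table


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Columns holding marker intensities, in table order."""
    return [c for c in table.columns if c not in RESERVED_COLUMNS]


def read_cell_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if len(table) == 0 and list(table.columns) == [] :
        raise FormatError(f"{path}: empty file, not a cell table")
    return validate_cell_table(table)


def write_cell_table(table: pd.DataFrame, path) -> None:
    validate_cell_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")
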