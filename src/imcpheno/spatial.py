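"""Nearest-neighbor distances and per-ROI median distance from tumor cells.

Distances are Euclidean between cell centroids, in micrometers, computed
within each sample/ROI independently (cells never find neighbors across
ROIs).  The headline summary is the per-sample median distance of each
immune cell type to its nearest tumor cell.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_IMMUNE_TYPES = ("CD8", "CD4", "neutrophils", "macrophages")
DEFAULT_REFERENCE_TYPE = "tumor cells"


def nn_distances(
    table: pd.DataFrame,
    query_type: str,
    reference_type: str,
    annotation_col: str = "annotation",
) -> pd.Series:
    """Distance from each query-type cell to its nearest reference-type cell.

    Computed per sample; when query and reference types coincide each cell
    excludes itself.  Query cells in samples with no reference cell get NaN.
    Unknown type labels raise.
    """
    if annotation_col not in table.columns:
        raise ValueError(f"table lacks annotation column {annotation_col!r}")
    present = set(table[annotation_col])
    for t in (query_type, reference_type):
        if t not in present:
            raise ValueError(f"cell type {t!r} absent from column {annotation_col!r}")
    out = pd.Series(np.nan, index=table.index, dtype=float)
    same = query_type == reference_type
    for _, grp in table.groupby("sample_id"):
        q = grp[grp[annotation_col] == query_type]
        r = grp[grp[annotation_col] == reference_type]
        if len(q) == 0 or len(r) == 0 or (same and len(r) < 2):
            continue
        tree = cKDTree(r[["x_um", "y_um"]].to_numpy())
        if same:
            d, _ = tree.query(q[["x_um", "y_um"]].to_numpy(), k=2)
            out.loc[q.index] = d[:, 1]
        else:
            d, _ = tree.query(q[["x_um", "y_um"]].to_numpy(), k=1)
            out.loc[q.index] = d
    return out.loc[table[annotation_col] == query_type]


def summarize_median_distance(
    table: pd.DataFrame,
    immune_types: tuple[str, ...] = DEFAULT_IMMUNE_TYPES,
    reference_type: str = DEFAULT_REFERENCE_TYPE,
    annotation_col: str = "annotation",
) -> pd.DataFrame:
    """Per (sample, cell type): cell count and median nearest-tumor distance.

    Rows are omitted when a sample has no reference cells or no cells of the
    type; types entirely absent from the table are skipped rather than
    raised, so a fixed default type list works across panels.
    """
    present = set(table[annotation_col])
    rows = []
    for ctype in immune_types:
        if ctype not in present or reference_type not in present:
            continue
        d = nn_distances(table, ctype, reference_type, annotation_col)
        sub = table.loc[d.index]
        for sid, grp in sub.groupby("sample_id"):
            dists = d.loc[grp.index].dropna()
            if len(dists) == 0:
                continue
            rows.append(
                {
                    "sample_id": sid,
                    "cell_type": ctype,
                    "reference_type": reference_type,
                    "n_cells": len(dists),
                    "median_distance_um": float(dists.median()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "cell_type", "reference_type", "n_cells",
                 "median_distance_um"],
    )
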