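"""Per-cell marker quantification and the log + double z-score normalization.

Quantification sums each marker's pixel intensities over every segmented
cell, yielding the cell-by-protein matrix.  Normalization then applies
ln(1 + x), standardizes each marker column across cells, and finally
standardizes each cell row across markers.  The column-then-row order follows
the convention that "across cells" / "across markers" name the dimension over
which mean and SD are taken; the opposite order is available via ``order``
because the prose convention is genuinely ambiguous in the field.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateInputError
from .images import MultichannelImage
from .segmentation import SegmentationMask
from .panel import MarkerPanel
from .tables import marker_columns


def quantify(
    image: MultichannelImage,
    mask: SegmentationMask,
    panel: MarkerPanel,
    sample_id: str = "sample",
    condition: str = "control",
) -> pd.DataFrame:
    """Cell-by-protein table: total intensity per marker per labeled cell.

    One row per positive label, with the area-weighted centroid in
    micrometers, pixel area, and sample/condition metadata.
    """
    if image.shape != mask.labels.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {mask.labels.shape}"
        )
    n = mask.n_cells
    ids = np.arange(1, n + 1)
    cols: dict[str, np.ndarray] = {}
    if n == 0:
        empty = pd.DataFrame(
            columns=["cell_id", "x_um", "y_um", "area_px", "sample_id", "condition"]
            + [m for m in panel.markers if m in image.channels]
        )
        return empty

    labels = mask.labels
    area = ndimage.sum_labels(np.ones_like(labels, dtype=np.float64), labels, ids)
    coms = ndimage.center_of_mass(np.ones_like(labels, dtype=np.float64), labels, ids)
    coms = np.asarray(coms)  # (n, 2) as (row, col)
    cols["cell_id"] = ids
    cols["x_um"] = coms[:, 1] * image.pixel_size_um
    cols["y_um"] = coms[:, 0] * image.pixel_size_um
    cols["area_px"] = area.astype(np.int64)
    cols["sample_id"] = np.repeat(sample_id, n)
    cols["condition"] = np.repeat(condition, n)
    for m in panel.markers:
        if m in image.channels:
            cols[m] = ndimage.sum_labels(image.channels[m], labels, ids)
    return pd.DataFrame(cols)


@dataclass
class NormalizedMatrix:
    """Doubly standardized cell-by-marker matrix plus its transform provenance."""

    values: pd.DataFrame  # same index as the source table, marker columns
    provenance: list[str] = field(default_factory=list)

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)


def _zscore(arr: np.ndarray, axis: int) -> np.ndarray:
    """Standardize along ``axis`` with sample SD; constant vectors map to 0."""
    mean = arr.mean(axis=axis, keepdims=True)
    sd = arr.std(axis=axis, ddof=1, keepdims=True)
    out = np.zeros_like(arr)
    np.divide(arr - mean, sd, out=out, where=sd > 0)
    return out


def normalize(
    table: pd.DataFrame,
    markers: list[str] | None = None,
    order: tuple[str, str] = ("across_cells", "across_markers"),
) -> NormalizedMatrix:
    """ln(1 + x) then two sequential z-score passes over the marker block.

    ``order`` names the two standardization passes: ``"across_cells"``
    standardizes each marker column over cells, ``"across_markers"``
    standardizes each cell row over markers.  Requires at least 2 cells.
    """
    if markers is None:
        markers = marker_columns(table)
    if len(table) < 2:
        raise DegenerateInputError("normalization needs at least 2 cells")
    if set(order) != {"across_cells", "across_markers"}:
        raise ValueError(f"order must contain both passes, got {order}")
    X = table[markers].to_numpy(dtype=np.float64)
    if (X < 0).any():
        raise ValueError("marker intensities must be nonnegative before log transform")
    X = np.log1p(X)
    provenance = ["log1p"]
    for step in order:
        axis = 0 if step == "across_cells" else 1
        X = _zscore(X, axis=axis)
        provenance.append(f"zscore_{step}")
    values = pd.DataFrame(X, index=table.index, columns=markers)
    return NormalizedMatrix(values=values, provenance=provenance)
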