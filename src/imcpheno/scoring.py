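"""Serial-section metastatic-burden scoring.

Each lesion measured on an H&E serial section is scored by its diameter:
<1 mm scores 1, 1-3 mm scores 2, 3-5 mm scores 3 and >=5 mm scores 4.  Bin
edges are half-open, [low, high), with the top bin closed below at 5 mm.  A
sample's metastatic burden is the sum of lesion scores over all its sections
(typically 10 sections cut every 150 um).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BIN_EDGES_MM = np.array([1.0, 3.0, 5.0])


def score_lesion(diameter_mm: float) -> int:
    """Size-bin score of one lesion: <1, [1,3), [3,5), >=5 mm -> 1, 2, 3, 4."""
    if not diameter_mm > 0:
        raise ValueError(f"lesion diameter must be positive, got {diameter_mm}")
    return int(np.searchsorted(_BIN_EDGES_MM, diameter_mm, side="right")) + 1


@dataclass
class ScoreReport:
    sample_id: str
    total_score: int
    n_lesions: int
    per_lesion: pd.DataFrame  # section_index, diameter_mm, score
    per_section: pd.DataFrame  # section_index, subtotal, n_lesions


def score_sample(lesions: pd.DataFrame) -> ScoreReport:
    """Score all lesions of one sample and sum over its sections.

    ``lesions`` needs columns sample_id, section_index, diameter_mm and must
    contain a single sample.  An empty frame scores 0.
    """
    if len(lesions) == 0:
        return ScoreReport(
            sample_id="",
            total_score=0,
            n_lesions=0,
            per_lesion=pd.DataFrame(columns=["section_index", "diameter_mm", "score"]),
            per_section=pd.DataFrame(columns=["section_index", "subtotal", "n_lesions"]),
        )
    ids = lesions["sample_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"score_sample got mixed sample_ids: {sorted(ids)}")
    per_lesion = lesions[["section_index", "diameter_mm"]].copy()
    per_lesion["score"] = [score_lesion(d) for d in per_lesion["diameter_mm"]]
    per_section = (
        per_lesion.groupby("section_index")
        .agg(subtotal=("score", "sum"), n_lesions=("score", "size"))
        .reset_index()
    )
    return ScoreReport(
        sample_id=str(ids[0]),
        total_score=int(per_lesion["score"].sum()),
        n_lesions=len(per_lesion),
        per_lesion=per_lesion,
        per_section=per_section,
    )


def score_table(lesions: pd.DataFrame) -> pd.DataFrame:
    """Per-sample totals for a multi-sample lesion table."""
    rows = []
    for sid, grp in lesions.groupby("sample_id", sort=True):
        rep = score_sample(grp)
        rows.append(
            {"sample_id": sid, "total_score": rep.total_score, "n_lesions": rep.n_lesions}
        )
    return pd.DataFrame(rows, columns=["sample_id", "total_score", "n_lesions"])
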