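"""Differential-state testing of per-cluster marker expression between
conditions, on sample-level medians.

For every (cluster, marker) pair the per-sample median expression is
computed, and the two conditions are compared by an ordinary two-sample
t-test on those medians; p-values are adjusted jointly across all tested
pairs by the Benjamini-Hochberg step-up procedure.  Testing sample medians
keeps the ROI (not the cell) as the unit of replication, matching designs
with as few as 3 ROIs per arm.  Unlike moderated-variance approaches, the
plain t-test shares no information across pairs; with n = 3 per arm this is
deliberately transparent but low-powered (see docs/methods.md).

A pair is reported untested (NaN p) when either condition contributes fewer
than 2 samples with cells in that cluster.  The degenerate case of two
literally identical condition groups (zero difference, zero variance) is
assigned p = 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantification import NormalizedMatrix, normalize
from .tables import marker_columns


class DifferentialStateModel:
    """Condition contrast of per-cluster marker expression.

    Parameters
    ----------
    table : DataFrame
        Cell table with ``cluster``, ``sample_id`` and ``condition`` columns.
    condition_a, condition_b : str
        The two condition labels to contrast; the estimate is
        mean(medians | b) - mean(medians | a).
    values : NormalizedMatrix or DataFrame, optional
        Expression values aligned to ``table`` rows.  By default the marker
        block of ``table`` is normalized (the same matrix fed to clustering);
        pass ``use_raw=True`` to take raw totals instead.
    """

    def __init__(self, table: pd.DataFrame, condition_a: str, condition_b: str,
                 values=None, use_raw: bool = False, cluster_col: str = "cluster"):
        for col in (cluster_col, "sample_id", "condition"):
            if col not in table.columns:
                raise ValueError(f"table lacks required column {col!r}")
        conds = set(table["condition"])
        for c in (condition_a, condition_b):
            if c not in conds:
                raise ValueError(f"condition {c!r} absent from table")
        self.table = table
        self.condition_a = condition_a
        self.condition_b = condition_b
        self.cluster_col = cluster_col
        markers = marker_columns(table)
        if values is None:
            values = table[markers] if use_raw else normalize(table, markers).values
        elif isinstance(values, NormalizedMatrix):
            values = values.values
        self.values: pd.DataFrame = values

    def fit(self) -> "DSResults":
        tab = self.table
        markers = list(self.values.columns)
        sample_cond = tab.groupby("sample_id")["condition"].first()
        samples_a = sample_cond[sample_cond == self.condition_a].index
        samples_b = sample_cond[sample_cond == self.condition_b].index

        df = self.values.copy()
        df[self.cluster_col] = tab[self.cluster_col].to_numpy()
        df["sample_id"] = tab["sample_id"].to_numpy()
        medians = df.groupby([self.cluster_col, "sample_id"])[markers].median()

        rows = []
        for cluster in sorted(tab[self.cluster_col].unique()):
            block = medians.loc[cluster]
            a = block.reindex(samples_a).dropna(how="all")
            b = block.reindex(samples_b).dropna(how="all")
            na, nb = len(a), len(b)
            if na >= 2 and nb >= 2:
                A, B = a.to_numpy(), b.to_numpy()
                est = B.mean(axis=0) - A.mean(axis=0)
                p = stats.ttest_ind(B, A, axis=0, equal_var=True).pvalue
                # identical degenerate groups: zero difference, zero variance
                flat = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
                p = np.where(flat, np.where(est == 0, 1.0, 0.0), p)
            else:
                est = np.full(len(markers), np.nan)
                p = np.full(len(markers), np.nan)
            for j, m in enumerate(markers):
                rows.append(
                    {"cluster": cluster, "marker": m,
                     "n_samples_a": na, "n_samples_b": nb,
                     "estimate": float(est[j]), "p_value": float(p[j])}
                )
        frame = pd.DataFrame(rows)
        frame["adjusted_p"] = bh_adjust(frame["p_value"].to_numpy())
        return DSResults(self, frame)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaN entries stay NaN and do not
    count toward the number of tests."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class DSResults:
    """Differential-state results: one row per (cluster, marker)."""

    model: DifferentialStateModel
    frame: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def significant(self, level: float = 0.05) -> pd.DataFrame:
        f = self.frame
        return f[f["adjusted_p"] < level].sort_values("adjusted_p")

    def summary(self, max_rows: int = 20) -> str:
        f = self.frame.sort_values("adjusted_p", na_position="last")
        lines = [
            "Differential-state results",
            "==========================",
            f"contrast: {self.model.condition_b} - {self.model.condition_a} "
            "(difference of condition means of per-sample medians)",
            f"pairs tested: {int(f['p_value'].notna().sum())} of {len(f)}",
            "",
            f"{'cluster':>7} {'marker':<12} {'estimate':>9} {'p':>8} {'adj. p':>8}",
        ]
        for _, r in f.head(max_rows).iterrows():
            lines.append(
                f"{r['cluster']:>7} {str(r['marker']):<12} "
                f"{r['estimate']:>9.3f} {r['p_value']:>8.4f} {r['adjusted_p']:>8.4f}"
            )
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def ds_test(
    table: pd.DataFrame, condition_a: str, condition_b: str, **kwargs
) -> DSResults:
    """Functional wrapper: fit a DifferentialStateModel in one call."""
    return DifferentialStateModel(table, condition_a, condition_b, **kwargs).fit()
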