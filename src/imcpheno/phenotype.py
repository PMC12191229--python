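"""Cell phenotyping: high-restart K-means, one-vs-one differential markers,
marker-list naming and rule-based annotation.

The model clusters the normalized cell-by-marker matrix with Lloyd's
algorithm restarted from many random initializations, keeping the restart
with the smallest within-cluster sum of squares — the high-restart strategy
that makes K-means robust to initialization on cytometry data.  Each cluster
is then characterized by its differential markers: a marker is called
differential for a cluster when a one-sided criterion (rank-sum p < alpha
and higher median in the cluster) holds against at least ``min_significant``
of the other k - 1 clusters.  At the default threshold min_significant =
k - 3, a 20-cluster fit requires significance in 17 of 19 one-vs-one
comparisons.  Clusters are named by their differential-marker lists and
annotated by ordered marker rules (neutrophils: S100A8/S100A9; macrophages:
F4/80; tumor cells: Vimentin/CD44; otherwise "unidentified").
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import mannwhitneyu

from .quantification import NormalizedMatrix

logger = logging.getLogger(__name__)

UNNAMED = "unnamed"  # placeholder for a cluster with no differential markers
UNIDENTIFIED = "unidentified"  # annotation fallback


def min_significant_for(k: int) -> int:
    """Default one-vs-one threshold: k - 3 of the k - 1 comparisons (>= 1).

    At k = 20 this requires 17 of 19 significant comparisons.
    """
    if k < 2:
        raise ValueError("need at least 2 clusters")
    return max(k - 3, 1)


# --------------------------------------------------------------------- K-means
def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int = 300):
    """Lloyd iterations to convergence; empty clusters are reseeded at the
    point farthest from its current centroid."""
    n, _ = X.shape
    k = centroids.shape[0]
    assign = np.full(n, -1)
    for _ in range(max_iter):
        d2 = cdist(X, centroids, "sqeuclidean")
        new_assign = d2.argmin(axis=1)
        # reseed any empty cluster at the point farthest from its own centroid
        for c in range(k):
            if not (new_assign == c).any():
                far = d2[np.arange(n), new_assign].argmax()
                new_assign[far] = c
                centroids[c] = X[far]
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            centroids[c] = X[assign == c].mean(axis=0)
    d2 = cdist(X, centroids, "sqeuclidean")
    obj = float(d2[np.arange(n), assign].sum())
    return assign, centroids, obj


def kmeans_cluster(
    X: np.ndarray, k: int, n_restarts: int = 100, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_restarts`` Lloyd K-means.

    Initial centroids of each restart are k distinct rows drawn from one RNG
    stream seeded by ``seed``, so the result is deterministic and the best
    objective is non-increasing in ``n_restarts``.  Returns (assignments in
    1..k, centroids, within-cluster sum of squares).
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    if k < 1 or n_restarts < 1:
        raise ValueError("k and n_restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        assign, centroids, obj = _lloyd(X, X[idx].copy())
        if best is None or obj < best[2] - 1e-12:
            best = (assign, centroids, obj)
    assign, centroids, obj = best
    return assign + 1, centroids, obj


@dataclass
class DifferentialMarkerMap:
    """Per-cluster differential markers and the derived names/annotations."""

    counts: pd.DataFrame  # clusters x markers, significant-comparison counts
    differential: dict[int, list[str]]  # ordered by count desc then panel order
    min_significant: int
    alpha: float
    names: dict[int, str] = field(default_factory=dict)
    annotations: dict[int, str] = field(default_factory=dict)


class PhenotypeModel:
    """K-means phenotyping model over a normalized cell-by-marker matrix.

    Parameters
    ----------
    matrix : NormalizedMatrix or DataFrame
        Cells x markers, typically the log + doubly z-scored matrix.
    k : int
        Number of clusters (default 20).
    n_restarts : int
        Random restarts; the study-scale setting is 100,000, the desk-scale
        default is 100.
    seed : int
        Seed of the single RNG stream driving all restarts.
    """

    def __init__(self, matrix, k: int = 20, n_restarts: int = 100, seed: int = 0):
        if isinstance(matrix, NormalizedMatrix):
            matrix = matrix.values
        self.data: pd.DataFrame = matrix
        self.k = int(k)
        self.n_restarts = int(n_restarts)
        self.seed = int(seed)
        if self.k > len(matrix):
            raise ValueError(f"k={k} exceeds the number of cells ({len(matrix)})")

    def fit(self) -> "PhenotypeResults":
        assign, centroids, obj = kmeans_cluster(
            self.data.to_numpy(), self.k, self.n_restarts, self.seed
        )
        assignments = pd.Series(assign, index=self.data.index, name="cluster")
        centroids = pd.DataFrame(
            centroids, index=pd.RangeIndex(1, self.k + 1, name="cluster"),
            columns=self.data.columns,
        )
        return PhenotypeResults(self, assignments, centroids, obj)


@dataclass(frozen=True)
class AnnotationRule:
    label: str
    markers: frozenset[str]
    mode: str = "any"  # "any": intersects; "all": subset of differential list


def default_annotation_rules() -> list[AnnotationRule]:
    return [
        AnnotationRule("neutrophils", frozenset({"S100A8", "S100A9"})),
        AnnotationRule("macrophages", frozenset({"F4/80"})),
        AnnotationRule("tumor cells", frozenset({"Vimentin", "CD44"})),
    ]


class PhenotypeResults:
    """Fitted phenotyping: assignments, centroids, objective, and the
    differential-marker machinery."""

    def __init__(self, model: PhenotypeModel, assignments: pd.Series,
                 centroids: pd.DataFrame, objective: float):
        self.model = model
        self.assignments = assignments
        self.centroids = centroids
        self.objective = objective

    @property
    def k(self) -> int:
        return self.model.k

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().reindex(
            range(1, self.k + 1), fill_value=0
        ).sort_index()

    # ------------------------------------------------- differential markers
    def differential_markers(
        self, alpha: float = 0.05, min_significant: int | None = None
    ) -> DifferentialMarkerMap:
        """One-vs-one differential-marker calling.

        For every cluster c and marker m, each other cluster is compared by a
        two-sided Wilcoxon rank-sum test; the comparison counts as significant
        only if p < alpha and the median of m in c exceeds the median in the
        other cluster ("expressed in" the cluster means upregulated).  m is
        differential for c iff at least ``min_significant`` of the k - 1
        comparisons are significant (default k - 3).
        """
        X = self.model.data
        k = self.k
        if min_significant is None:
            min_significant = min_significant_for(k)
        groups = {c: X[self.assignments == c] for c in range(1, k + 1)}
        small = [c for c, g in groups.items() if len(g) < 2]
        if small:
            logger.warning(
                "clusters %s have <2 cells; their comparisons count as "
                "non-significant", small,
            )
        markers = list(X.columns)
        counts = pd.DataFrame(
            0, index=pd.RangeIndex(1, k + 1, name="cluster"), columns=markers,
            dtype=int,
        )
        for c in range(1, k + 1):
            gc = groups[c]
            if len(gc) < 2:
                continue
            for other in range(1, k + 1):
                if other == c or len(groups[other]) < 2:
                    continue
                go = groups[other]
                for m in markers:
                    a, b = gc[m].to_numpy(), go[m].to_numpy()
                    if np.median(a) <= np.median(b):
                        continue
                    p = mannwhitneyu(a, b, alternative="two-sided").pvalue
                    if p < alpha:
                        counts.loc[c, m] += 1
        panel_order = {m: i for i, m in enumerate(markers)}
        differential = {}
        for c in range(1, k + 1):
            hits = [m for m in markers if counts.loc[c, m] >= min_significant]
            hits.sort(key=lambda m: (-counts.loc[c, m], panel_order[m]))
            differential[c] = hits
        dmap = DifferentialMarkerMap(
            counts=counts, differential=differential,
            min_significant=min_significant, alpha=alpha,
        )
        name_clusters(dmap)
        annotate_clusters(dmap)
        return dmap

    # ----------------------------------------------------------- reporting
    def summary(self, dmap: DifferentialMarkerMap | None = None) -> str:
        lines = [
            "Phenotyping results",
            "===================",
            f"cells: {len(self.assignments)}   markers: {self.model.data.shape[1]}",
            f"k: {self.k}   restarts: {self.model.n_restarts}   seed: {self.model.seed}",
            f"within-cluster sum of squares: {self.objective:.4f}",
            "",
            f"{'cluster':>7} {'n':>6}  name / annotation",
        ]
        sizes = self.cluster_sizes()
        for c in range(1, self.k + 1):
            extra = ""
            if dmap is not None:
                extra = f"{dmap.names.get(c, '')} [{dmap.annotations.get(c, '')}]"
            lines.append(f"{c:>7} {sizes[c]:>6}  {extra}")
        return "\n".join(lines)

    def plot_centroids(self, ax=None):
        """Heatmap of cluster centroids (clusters x markers)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 0.4 * self.k + 2))
        im = ax.imshow(self.centroids.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(self.centroids.columns)))
        ax.set_xticklabels(self.centroids.columns, rotation=90)
        ax.set_yticks(range(self.k))
        ax.set_yticklabels(self.centroids.index)
        ax.set_ylabel("cluster")
        ax.figure.colorbar(im, ax=ax, label="centroid (z units)")
        return ax


def name_clusters(dmap: DifferentialMarkerMap) -> dict[int, str]:
    """Name each cluster by its differential markers joined with "/".

    Markers appear in descending significant-comparison count, ties broken by
    panel order (already encoded in the differential lists).  A cluster with
    no differential markers receives the placeholder name ``unnamed``,
    distinct from the ``unidentified`` annotation fallback.
    """
    names = {
        c: "/".join(ms) if ms else UNNAMED for c, ms in dmap.differential.items()
    }
    dmap.names = names
    return names


def annotate_clusters(
    dmap: DifferentialMarkerMap, rules: list[AnnotationRule] | None = None
) -> dict[int, str]:
    """Apply ordered marker rules; the first matching rule labels the cluster."""
    if rules is None:
        rules = default_annotation_rules()
    labels = {r.label for r in rules}
    if len(labels) != len(rules):
        raise ValueError("annotation rule labels must be unique")
    annotations = {}
    for c, ms in dmap.differential.items():
        mset = set(ms)
        label = UNIDENTIFIED
        for rule in rules:
            hit = (rule.markers <= mset) if rule.mode == "all" else bool(rule.markers & mset)
            if hit:
                label = rule.label
                break
        annotations[c] = label
    dmap.annotations = annotations
    return annotations
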