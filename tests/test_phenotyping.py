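"""K-means clustering, the one-vs-one differential-marker rule, naming and
annotation, including brute-force and sklearn cross-checks."""
import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from imcpheno import (
    AnnotationRule,
    PhenotypeModel,
    annotate_clusters,
    kmeans_cluster,
    min_significant_for,
    name_clusters,
    normalize,
)
from imcpheno.phenotype import UNIDENTIFIED, UNNAMED, DifferentialMarkerMap


def two_blob_data(n=40, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n // 2, 3))
    b = rng.normal(sep, 1, (n - n // 2, 3))
    return np.vstack([a, b]), np.r_[np.zeros(n // 2), np.ones(n - n // 2)]


class TestKMeans:
    def test_k1_objective_is_total_ss(self):
        X, _ = two_blob_data()
        _, _, obj = kmeans_cluster(X, k=1, n_restarts=3, seed=0)
        expected = ((X - X.mean(axis=0)) ** 2).sum()
        assert obj == pytest.approx(expected)

    def test_separated_blobs_recovered_exactly(self):
        X, truth = two_blob_data(sep=10.0)
        assign, _, _ = kmeans_cluster(X, k=2, n_restarts=10, seed=1)
        assert adjusted_rand_score(truth, assign) == 1.0

    def test_deterministic_given_seed(self):
        X, _ = two_blob_data(n=60, sep=2.0)
        r1 = kmeans_cluster(X, k=4, n_restarts=5, seed=3)
        r2 = kmeans_cluster(X, k=4, n_restarts=5, seed=3)
        assert np.array_equal(r1[0], r2[0])
        assert r1[2] == r2[2]

    def test_objective_non_increasing_in_restarts(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (50, 4))
        objs = [
            kmeans_cluster(X, k=5, n_restarts=r, seed=11)[2] for r in (1, 3, 10, 30)
        ]
        assert objs == sorted(objs, reverse=True) or all(
            a >= b - 1e-9 for a, b in zip(objs, objs[1:])
        )

    def test_matches_exhaustive_minimum_small_n(self):
        # brute-force oracle over all bipartitions of n <= 12 points
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (10, 2))

        def ss(idx):
            sub = X[list(idx)]
            return ((sub - sub.mean(axis=0)) ** 2).sum()

        best = np.inf
        pts = range(len(X))
        for r in range(1, len(X) // 2 + 1):
            for group in itertools.combinations(pts, r):
                rest = tuple(p for p in pts if p not in group)
                best = min(best, ss(group) + ss(rest))
        _, _, obj = kmeans_cluster(X, k=2, n_restarts=50, seed=0)
        assert obj == pytest.approx(best, rel=1e-9)

    def test_agrees_with_sklearn_on_easy_data(self):
        from sklearn.cluster import KMeans

        X, _ = two_blob_data(n=80, sep=8.0, seed=2)
        assign, _, obj = kmeans_cluster(X, k=2, n_restarts=10, seed=0)
        sk = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert obj == pytest.approx(sk.inertia_, rel=1e-6)
        assert adjusted_rand_score(sk.labels_, assign) == 1.0

    def test_k_larger_than_n_rejected(self):
        X, _ = two_blob_data(n=6)
        with pytest.raises(ValueError):
            kmeans_cluster(X, k=7, n_restarts=1, seed=0)


class TestMinSignificant:
    def test_k20_requires_17_of_19(self):
        assert min_significant_for(20) == 17

    @pytest.mark.parametrize("k,expected", [(2, 1), (4, 1), (5, 2), (10, 7)])
    def test_generalized_threshold(self, k, expected):
        assert min_significant_for(k) == expected


def cluster_grid_model(counts_per_cluster, shifts, seed=0):
    """Build a PhenotypeResults-like setup: Gaussian markers with specified
    per-cluster mean shifts (dict marker -> {cluster: shift})."""
    rng = np.random.default_rng(seed)
    k = len(counts_per_cluster)
    markers = sorted({m for m in shifts})
    rows, assign = [], []
    for c, n in enumerate(counts_per_cluster, start=1):
        X = rng.normal(0, 1, (n, len(markers)))
        for j, m in enumerate(markers):
            X[:, j] += shifts[m].get(c, 0.0)
        rows.append(X)
        assign += [c] * n
    data = pd.DataFrame(np.vstack(rows), columns=markers)
    model = PhenotypeModel.__new__(PhenotypeModel)
    model.data = data
    model.k = k
    model.n_restarts = 1
    model.seed = seed
    from imcpheno.phenotype import PhenotypeResults

    res = PhenotypeResults(
        model, pd.Series(assign, index=data.index, name="cluster"),
        centroids=data.groupby(assign).mean(), objective=0.0,
    )
    return res


class TestDifferentialMarkers:
    def test_marker_elevated_in_one_of_20_clusters(self):
        res = cluster_grid_model([25] * 20, {"CD44": {1: 6.0}}, seed=1)
        dmap = res.differential_markers()
        assert dmap.min_significant == 17
        assert dmap.counts.loc[1, "CD44"] == 19
        assert "CD44" in dmap.differential[1]
        assert all("CD44" not in dmap.differential[c] for c in range(2, 21))

    def test_identically_distributed_marker_not_differential(self):
        res = cluster_grid_model([30] * 6, {"CD4": {}}, seed=2)
        dmap = res.differential_markers()
        assert (dmap.counts["CD4"] < dmap.min_significant).all()

    def test_elevated_against_too_few_clusters_not_called(self):
        # marker high in cluster 1 *and* in clusters 2..4 of a 20-cluster fit:
        # only 16 of 19 comparisons can be significant, below the 17 threshold
        shifts = {"F4/80": {1: 6.0, 2: 6.0, 3: 6.0, 4: 6.0}}
        res = cluster_grid_model([25] * 20, shifts, seed=3)
        dmap = res.differential_markers()
        assert dmap.counts.loc[1, "F4/80"] == 16
        assert "F4/80" not in dmap.differential[1]

    def test_counts_verified_by_per_comparison_oracle(self):
        from scipy.stats import mannwhitneyu

        res = cluster_grid_model([20] * 4, {"CD8a": {1: 3.0, 2: 1.0}}, seed=4)
        dmap = res.differential_markers(alpha=0.05)
        X, assign = res.model.data, res.assignments
        for c in range(1, 5):
            count = 0
            a = X.loc[assign == c, "CD8a"]
            for o in range(1, 5):
                if o == c:
                    continue
                b = X.loc[assign == o, "CD8a"]
                p = mannwhitneyu(a, b, alternative="two-sided").pvalue
                count += (p < 0.05) and (a.median() > b.median())
            assert dmap.counts.loc[c, "CD8a"] == count

    def test_tiny_cluster_comparisons_skipped(self, caplog):
        res = cluster_grid_model([1, 20, 20], {"CD4": {2: 5.0}}, seed=5)
        with caplog.at_level("WARNING"):
            dmap = res.differential_markers()
        assert (dmap.counts.loc[1] == 0).all()
        assert "have <2 cells" in caplog.text


def make_dmap(differential, counts=None):
    clusters = sorted(differential)
    markers = sorted({m for ms in differential.values() for m in ms}) or ["CD4"]
    frame = pd.DataFrame(0, index=clusters, columns=markers)
    if counts:
        for (c, m), v in counts.items():
            frame.loc[c, m] = v
    return DifferentialMarkerMap(
        counts=frame, differential=differential, min_significant=1, alpha=0.05
    )


class TestNamingAndAnnotation:
    def test_name_joins_markers_by_count_order(self):
        dmap = make_dmap({1: ["F4/80", "CD68"]}, {(1, "F4/80"): 19, (1, "CD68"): 18})
        assert name_clusters(dmap)[1] == "F4/80/CD68"

    def test_empty_list_gets_placeholder_distinct_from_fallback(self):
        dmap = make_dmap({1: []})
        names = name_clusters(dmap)
        assert names[1] == UNNAMED
        assert names[1] != UNIDENTIFIED

    def test_tie_broken_by_panel_order(self):
        # equal counts: differential lists already sorted by (count, position)
        dmap = make_dmap({1: ["CD4", "CD8a"]}, {(1, "CD4"): 5, (1, "CD8a"): 5})
        assert name_clusters(dmap)[1] == "CD4/CD8a"

    def test_neutrophil_rule_fires_on_s100a8(self):
        dmap = make_dmap({1: ["S100A8", "Ly6G"]})
        assert annotate_clusters(dmap)[1] == "neutrophils"

    def test_unmatched_cluster_unidentified(self):
        dmap = make_dmap({1: ["CD62L"]})
        assert annotate_clusters(dmap)[1] == UNIDENTIFIED

    def test_rule_order_decides_overlaps(self):
        dmap = make_dmap({1: ["S100A9", "F4/80"]})
        assert annotate_clusters(dmap)[1] == "neutrophils"

    def test_custom_rule_all_mode(self):
        dmap = make_dmap({1: ["Vimentin"], 2: ["Vimentin", "CD44"]})
        rules = [AnnotationRule("tumor cells", frozenset({"Vimentin", "CD44"}), "all")]
        ann = annotate_clusters(dmap, rules)
        assert ann == {1: UNIDENTIFIED, 2: "tumor cells"}


class TestModelOnSyntheticTable:
    def test_five_phenotypes_recovered(self, six_sample_table):
        table, truth = six_sample_table
        res = PhenotypeModel(normalize(table), k=5, n_restarts=20, seed=0).fit()
        ari = adjusted_rand_score(
            truth["phenotype"].to_numpy(), res.assignments.to_numpy()
        )
        assert ari >= 0.90
        # objective equals recomputed within-cluster SS of the assignment
        X = res.model.data.to_numpy()
        recomputed = sum(
            ((X[res.assignments.to_numpy() == c]
              - X[res.assignments.to_numpy() == c].mean(axis=0)) ** 2).sum()
            for c in range(1, 6)
        )
        assert res.objective == pytest.approx(recomputed, rel=1e-6)

    def test_defining_markers_called_differential(self, six_sample_table, panel):
        table, truth = six_sample_table
        res = PhenotypeModel(normalize(table), k=5, n_restarts=20, seed=0).fit()
        dmap = res.differential_markers()
        # map clusters to their majority true phenotype
        majority = (
            pd.crosstab(res.assignments.to_numpy(), truth["phenotype"].to_numpy())
            .idxmax(axis=1)
        )
        defining = {
            "tumor": ["Vimentin", "CD44"],
            "macrophage": ["F4/80"],
            "neutrophil": ["S100A8", "S100A9"],
            "t_cell": ["CD4", "CD8a"],
            "b_cell": ["B220"],
        }
        for c, pheno in majority.items():
            for m in defining[pheno]:
                assert m in dmap.differential[c], (c, pheno, m)

    def test_summary_mentions_counts_and_names(self, six_sample_table):
        table, _ = six_sample_table
        res = PhenotypeModel(normalize(table), k=5, n_restarts=5, seed=0).fit()
        dmap = res.differential_markers()
        text = res.summary(dmap)
        assert "within-cluster sum of squares" in text
        assert "k: 5" in text
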