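"""Metrics, stratified analyses, naive baselines, ARI and clustering."""

import numpy as np
import pytest

from promethyl.evaluation import (
    ari,
    cluster_cells,
    compute_metrics,
    degree_analysis,
    error_by_true_level,
    naive_predictor,
    rank_promoters_by_ari,
    true_level_distribution,
)
from promethyl.graphs import PromoterGraph
from promethyl.core import TargetRegion

from oracles import ap_recall_increment, ari_contingency, auc_mann_whitney, mcc_confusion


def _mask(n):
    return np.ones(n, dtype=bool)


class TestComputeMetrics:
    def test_perfect_predictor(self):
        true = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0.2, 0.9])
        r = compute_metrics(true, true, _mask(10))
        assert (r.pcc, r.mcc, r.average_precision, r.auc, r.mean_abs_error) == (
            1.0, 1.0, 1.0, 1.0, 0.0,
        )

    def test_anti_predictor(self):
        true = np.array([0.0, 1.0] * 5)
        r = compute_metrics(1 - true, true, _mask(10))
        assert r.pcc == pytest.approx(-1.0)
        assert r.auc == 0.0

    def test_matches_brute_force_oracles_on_toy_vectors(self):
        rng = np.random.default_rng(17)
        true = rng.random(20)
        pred = np.clip(true + rng.normal(0, 0.35, 20), 0, 1)
        r = compute_metrics(pred, true, _mask(20))
        labels = (true >= 0.5).astype(int)
        assert r.mcc == pytest.approx(mcc_confusion(labels, (pred >= 0.5).astype(int)))
        assert r.auc == pytest.approx(auc_mann_whitney(labels, pred))
        assert r.average_precision == pytest.approx(ap_recall_increment(labels, pred))
        assert r.mean_abs_error == pytest.approx(np.abs(pred - true).mean())
        assert r.pcc == pytest.approx(np.corrcoef(pred, true)[0, 1])

    def test_single_class_flagged_but_pcc_mae_computed(self):
        true = np.array([0.6, 0.7, 0.8, 0.95])
        pred = np.array([0.5, 0.6, 0.9, 0.9])
        r = compute_metrics(pred, true, _mask(4))
        assert r.single_class
        assert np.isnan(r.auc) and np.isnan(r.mcc) and np.isnan(r.average_precision)
        assert np.isfinite(r.pcc) and np.isfinite(r.mean_abs_error)

    def test_mask_filter_commutes_with_prefilter(self):
        rng = np.random.default_rng(3)
        pred, true = rng.random(30), rng.integers(0, 2, 30).astype(float)
        mask = rng.random(30) > 0.4
        full = compute_metrics(pred, true, mask)
        pre = compute_metrics(pred[mask], true[mask], _mask(mask.sum()))
        assert full == pre


class TestLevelStratification:
    def test_perfect_predictions_zero_in_every_bin(self):
        true = np.array([0.0, 0.05, 0.55, 1.0, 1.0])
        table = error_by_true_level(true, true, _mask(5))
        observed = table.dropna(subset=["mean_abs_error"])
        assert (observed["mean_abs_error"] == 0).all()

    def test_exact_zero_bin_isolated(self):
        true = np.zeros(4)
        pred = np.full(4, 0.3)
        table = error_by_true_level(pred, true, _mask(4))
        row = table[table["bin"] == "0"].iloc[0]
        assert row["count"] == 4 and row["mean_abs_error"] == pytest.approx(0.3)

    def test_hand_binning(self):
        true = np.array([0.0, 1.0, 0.10, 0.11, 0.95])
        pred = true + 0.01
        table = error_by_true_level(np.clip(pred, 0, 1), true, _mask(5))
        counts = dict(zip(table["bin"], table["count"]))
        # 0.10 falls in (0.0,0.1], 0.11 in (0.1,0.2], 0.95 in (0.9,1.0)
        assert counts["0"] == 1 and counts["1"] == 1
        assert counts["(0.0,0.1]"] == 1 and counts["(0.1,0.2]"] == 1
        assert counts["(0.9,1.0]"] == 1

    def test_distribution_fractions(self):
        true = np.array([1.0] * 3 + [0.0] * 3 + [0.4, 0.5])
        dist = true_level_distribution(true, _mask(8))
        by_bin = dict(zip(dist["bin"], dist["fraction"]))
        assert by_bin["0"] == pytest.approx(3 / 8)
        assert by_bin["1"] == pytest.approx(3 / 8)
        assert dist["fraction"].sum() == pytest.approx(1.0)

    def test_distribution_matches_counting_on_synthetic_truth(self, small_graphs):
        split, graph_sets = small_graphs
        g = graph_sets["train"][split["train"][0]][0]
        dist = true_level_distribution(g.targets, g.target_mask)
        levels = g.targets[g.target_mask]
        assert dist.loc[dist["bin"] == "0", "fraction"].iloc[0] == pytest.approx(
            (levels == 0).mean()
        )
        assert dist.loc[dist["bin"] == "1", "fraction"].iloc[0] == pytest.approx(
            (levels == 1).mean()
        )


def _graph_from_parts(agg, targets, mask, window=4):
    n = agg.shape[0]
    regions = [
        TargetRegion("g%d" % i, None, "+", (0, window), (0, window))
        for i in range(n)
    ]
    edges = [
        (i, j, np.zeros(3))
        for i in range(n) for j in range(i + 1, n) if agg[i, j] >= 1
    ]
    return PromoterGraph(
        cell_id="c", chrom="chr1", regions=regions,
        node_features=np.zeros((n, 2)), edges=edges,
        targets=targets, target_mask=mask, aggregated_counts=agg,
    )


class TestNaivePredictors:
    def _toy(self):
        agg = np.array(
            [[0, 2, 1, 0], [2, 0, 0, 0], [1, 0, 0, 0], [0, 0, 0, 0]]
        )
        targets = np.array(
            [[0.0] * 4, [1.0, 1.0, 0.0, 0.0], [0.0, 0.5, 1.0, 0.0], [0.2] * 4]
        )
        mask = np.array(
            [[1, 1, 1, 1], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]], dtype=bool
        )
        return _graph_from_parts(agg, targets, mask)

    def test_variant1_copies_most_connected_neighbor(self):
        g = self._toy()
        pred, pmask = naive_predictor(g, variant=1)
        np.testing.assert_array_equal(pred[0], g.targets[1])  # count 2 beats 1
        np.testing.assert_array_equal(pmask[0], g.target_mask[1])

    def test_single_neighbor_both_variants_copy_it(self):
        g = self._toy()
        p1, m1 = naive_predictor(g, variant=1)
        p2, m2 = naive_predictor(g, variant=2)
        np.testing.assert_array_equal(p1[1], g.targets[0])
        np.testing.assert_array_equal(p2[1][m2[1]], g.targets[0][m2[1]])

    def test_equal_weight_neighbors_average(self):
        agg = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        targets = np.array([[0.0] * 4, [0.0] * 4, [1.0] * 4])
        mask = np.ones((3, 4), dtype=bool)
        g = _graph_from_parts(agg, targets, mask)
        pred, pmask = naive_predictor(g, variant=2)
        np.testing.assert_allclose(pred[0], 0.5)
        assert pmask[0].all()

    def test_variant2_matches_hand_weighted_mean(self):
        g = self._toy()
        pred, pmask = naive_predictor(g, variant=2)
        # node 0: neighbors 1 (weight 2) and 2 (weight 1)
        # offset 0: both cover -> (2*1 + 1*0) / 3
        assert pred[0, 0] == pytest.approx(2 / 3)
        # offset 2: only node 2 covers -> its value 1.0
        assert pred[0, 2] == pytest.approx(1.0)
        # tie-break and masks
        assert pmask[0].tolist() == [True, True, True, False]

    def test_isolated_node_gets_no_prediction(self):
        g = self._toy()
        for variant in (1, 2):
            _, pmask = naive_predictor(g, variant=variant)
            assert not pmask[3].any()


class TestDegreeAnalysis:
    def test_star_graph_center_degree(self):
        n = 5
        agg = np.zeros((n, n), dtype=int)
        agg[0, 1:] = agg[1:, 0] = 1
        targets = np.tile(np.array([0.0, 1.0, 0.3, 0.8]), (n, 1))
        mask = np.ones((n, 4), dtype=bool)
        g = _graph_from_parts(agg, targets, mask)
        assert g.degrees()[0] == n - 1
        metrics, dist = degree_analysis([g], [targets])
        assert set(metrics["degree"]) == {1, n - 1}
        assert dict(zip(dist["degree"], dist["n_nodes"]))[1] == n - 1

    def test_all_isolated_graph_empty_analysis(self):
        agg = np.zeros((3, 3), dtype=int)
        g = _graph_from_parts(agg, np.zeros((3, 4)), np.ones((3, 4), bool))
        metrics, dist = degree_analysis([g], [np.zeros((3, 4))])
        assert metrics.empty
        assert dict(zip(dist["degree"], dist["n_nodes"])) == {0: 3}

    def test_per_degree_metrics_equal_subset_recomputation(self):
        rng = np.random.default_rng(8)
        agg = np.array([[0, 3, 0, 1], [3, 0, 2, 0], [0, 2, 0, 0], [1, 0, 0, 0]])
        targets = rng.integers(0, 2, (4, 6)).astype(float)
        mask = np.ones((4, 6), dtype=bool)
        g = _graph_from_parts(agg, targets, mask, window=6)
        pred = rng.random((4, 6))
        metrics, _ = degree_analysis([g], [pred])
        deg = g.degrees()
        for _, row in metrics.iterrows():
            nodes = np.flatnonzero(deg == row["degree"])
            sub = compute_metrics(pred[nodes].ravel(), targets[nodes].ravel(),
                                  np.ones(nodes.size * 6, bool))
            assert row["pcc"] == pytest.approx(sub.pcc, nan_ok=True)
            assert row["auc"] == pytest.approx(sub.auc, nan_ok=True)


class TestAri:
    def test_identical_labelings(self):
        assert ari([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_label_renaming_invariance(self):
        a = ["x", "x", "y", "y", "z"]
        b = [5, 5, 7, 7, 9]
        assert ari(a, b) == 1.0
        assert ari(a, b) == ari(b, a)

    def test_matches_contingency_formula_on_toy(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [0, 1, 1, 1, 2, 0]
        assert ari(a, b) == pytest.approx(ari_contingency(a, b))

    def test_random_labels_near_zero_mean(self):
        rng = np.random.default_rng(0)
        truth = [i % 4 for i in range(200)]
        scores = [
            ari(truth, rng.permutation(truth).tolist()) for _ in range(1000)
        ]
        assert abs(np.mean(scores)) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ari([1, 2], [1, 2, 3])


class TestClustering:
    def _blob_matrix(self, n_per=20, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.array([[0.1] * 6, [0.9] * 6])
        X = np.vstack([
            np.clip(centers[i] + rng.normal(0, 0.02, (n_per, 6)), 0, 1)
            for i in range(2)
        ])
        types = ["A"] * n_per + ["B"] * n_per
        return X, types

    def test_two_separated_types_perfect_ari(self):
        X, types = self._blob_matrix()
        report = cluster_cells(X, types, n_clusters=2, seed=0)
        assert report.ari_all_data == 1.0
        assert report.tsne_xy.shape == (40, 2)

    def test_fewer_cells_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_cells(np.zeros((3, 5)), ["A"] * 3, n_clusters=4)

    def test_identical_predictions_near_zero_ari(self):
        X = np.full((40, 6), 0.5)
        X += np.random.default_rng(1).normal(0, 1e-9, X.shape)
        types = ["A", "B"] * 20
        report = cluster_cells(X, types, n_clusters=2, seed=0)
        assert abs(report.ari_all_data) < 0.1


class TestPromoterRanking:
    def test_separating_promoter_ranks_first(self):
        rng = np.random.default_rng(4)
        types = ["A"] * 10 + ["B"] * 10
        separating = np.vstack([np.zeros((10, 3)), np.ones((10, 3))])
        noise1 = rng.random((20, 3))
        noise2 = rng.random((20, 3))
        ranking, curve = rank_promoters_by_ari(
            {"good": separating, "noise1": noise1, "noise2": noise2},
            types, n_clusters=2, seed=0,
        )
        assert ranking.iloc[0]["gene_id"] == "good"
        assert ranking.iloc[0]["ari_all_data"] == 1.0
        assert curve.iloc[0]["ari_all_data"] == 1.0

    def test_ranking_matches_exhaustive_per_promoter_ari(self):
        rng = np.random.default_rng(9)
        types = ["A"] * 8 + ["B"] * 8
        mats = {f"p{i}": rng.random((16, 2)) for i in range(5)}
        ranking, _ = rank_promoters_by_ari(mats, types, n_clusters=2, seed=3)
        from sklearn.cluster import KMeans

        for _, row in ranking.iterrows():
            km = KMeans(n_clusters=2, n_init=10, random_state=3)
            labels = km.fit_predict(mats[row["gene_id"]])
            assert row["ari_all_data"] == pytest.approx(ari(labels, types))
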