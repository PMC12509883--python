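"""Overlap-tolerant cluster metrics, partition agreement, cophenetic
correlation and enrichment tests."""

import math

import numpy as np
import pandas as pd
import pytest

from msclust.hierarchy import ClusterHierarchy, ClusterNode
from msclust.metrics import (
    ClusterSet,
    cophenetic_correlation,
    coverage_rate,
    detection_accuracy,
    fet_enrichment,
    hierarchy_cophenetic_matrix,
    inclusion_rate,
    layer_detection,
    network_stats,
    partition_agreement,
)

from conftest import clique_edges, graph_from_edges

UNIVERSE = {str(i) for i in range(1, 6)}
TRUTH = ClusterSet({"A": {"1", "2", "3"}, "B": {"4", "5"}}, set(UNIVERSE))
RESULT = ClusterSet({"X": {"1", "2"}, "Y": {"3", "4", "5"}}, set(UNIVERSE))


class TestOverlapMetrics:
    def test_identity_gives_one(self):
        t = ClusterSet({"A": {"1", "2"}, "B": {"3"}}, {"1", "2", "3"})
        r = ClusterSet({"A": {"1", "2"}, "B": {"3"}}, {"1", "2", "3"})
        assert inclusion_rate(r, t)[0] == 1
        assert coverage_rate(r, t)[0] == 1
        assert detection_accuracy(r, t)[0] == 1

    def test_worked_example(self):
        """Truth A={1,2,3}, B={4,5}; result X={1,2}, Y={3,4,5}:
        IR = CR = 0.8 and DA = 2/3 by direct enumeration."""
        ir, per_ir = inclusion_rate(RESULT, TRUTH)
        assert per_ir["X"] == 1 and per_ir["Y"] == pytest.approx(2 / 3)
        assert ir == pytest.approx(0.8)
        cr, per_cr = coverage_rate(RESULT, TRUTH)
        assert per_cr["A"] == pytest.approx(2 / 3) and per_cr["B"] == 1
        assert cr == pytest.approx(0.8)
        da, per_da = detection_accuracy(RESULT, TRUTH)
        assert per_da["A"] == pytest.approx(2 / 3)
        assert per_da["B"] == pytest.approx(2 / 3)
        assert da == pytest.approx(2 / 3)

    def test_singleton_results_have_perfect_inclusion(self):
        r = ClusterSet({str(i): {str(i)} for i in range(1, 6)}, set(UNIVERSE))
        assert inclusion_rate(r, TRUTH)[0] == 1

    def test_one_cluster_result_inflates_coverage(self):
        r = ClusterSet({"all": set(UNIVERSE)}, set(UNIVERSE))
        assert coverage_rate(r, TRUTH)[0] == 1

    def test_disjoint_result_zero_detection(self):
        t = ClusterSet({"A": {"1", "2"}}, set(UNIVERSE))
        r = ClusterSet({"X": {"3", "4"}}, set(UNIVERSE))
        assert detection_accuracy(r, t)[0] == 0

    def test_da_never_exceeds_cr(self):
        _, per_cr = coverage_rate(RESULT, TRUTH)
        _, per_da = detection_accuracy(RESULT, TRUTH)
        for name in per_cr:
            assert per_da[name] <= per_cr[name] + 1e-12

    def test_size_weighting_invariant_to_duplication(self):
        def dup(cs):
            return ClusterSet(
                {k: v | {c + "_dup" for c in v} for k, v in cs.clusters.items()},
                cs.universe | {c + "_dup" for c in cs.universe},
            )

        assert inclusion_rate(dup(RESULT), dup(TRUTH))[0] == pytest.approx(
            inclusion_rate(RESULT, TRUTH)[0]
        )
        assert detection_accuracy(dup(RESULT), dup(TRUTH))[0] == pytest.approx(
            detection_accuracy(RESULT, TRUTH)[0]
        )

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ClusterSet({"A": set()}, {"1"})


class TestPartitionAgreement:
    def test_identical_partitions(self):
        p = ClusterSet({"a": {"1", "2"}, "b": {"3", "4"}}, {"1", "2", "3", "4"})
        q = ClusterSet({"x": {"1", "2"}, "y": {"3", "4"}}, {"1", "2", "3", "4"})
        m = partition_agreement(p, q)
        assert m["ARI"] == 1 and m["NMI"] == 1
        assert m["purity"] == 0 and m["accuracy"] == 0

    def test_one_cluster_vs_two_equal_truth(self):
        r = ClusterSet({"all": {"1", "2", "3", "4"}}, {"1", "2", "3", "4"})
        t = ClusterSet({"a": {"1", "2"}, "b": {"3", "4"}}, {"1", "2", "3", "4"})
        m = partition_agreement(r, t)
        assert m["purity"] == pytest.approx(1.0)  # H = ln 2 normalized by ln 2

    def test_random_shuffle_ari_near_zero(self):
        rng = np.random.default_rng(0)
        cells = [str(i) for i in range(60)]
        truth_labels = np.repeat([0, 1, 2], 20)
        t = ClusterSet.from_labels(cells, truth_labels)
        aris = []
        for _ in range(100):
            r = ClusterSet.from_labels(cells, rng.permutation(truth_labels))
            aris.append(partition_agreement(r, t)["ARI"])
        assert abs(float(np.mean(aris))) < 0.05

    def test_non_partition_rejected(self):
        bad = ClusterSet({"a": {"1", "2"}, "b": {"2", "3"}}, {"1", "2", "3"})
        ok = ClusterSet({"a": {"1", "2", "3"}}, {"1", "2", "3"})
        with pytest.raises(ValueError):
            partition_agreement(bad, ok)


def _toy_hierarchy():
    """root -> {A: 0..3, B: 4..7}; A -> {A1: 0,1}; heights decrease."""
    h = ClusterHierarchy(cell_ids=[f"c{i}" for i in range(8)])
    h.root_compactness = 3.0
    h.nodes["M1"] = ClusterNode("M1", np.arange(0, 4), "root", 0.1, 2.0, 1.0, 0.01, 1)
    h.nodes["M2"] = ClusterNode("M2", np.arange(4, 8), "root", 0.1, 1.8, 1.0, 0.01, 1)
    h.nodes["M3"] = ClusterNode("M3", np.arange(0, 2), "M1", 0.5, 1.0, 0.9, 0.01, 2)
    return h


class TestCophenetic:
    def test_matrix_heights(self):
        D = hierarchy_cophenetic_matrix(_toy_hierarchy())
        assert D[0, 1] == pytest.approx(1.0)  # deepest shared node M3
        assert D[0, 3] == pytest.approx(2.0)  # LCA M1
        assert D[4, 5] == pytest.approx(1.8)
        assert D[0, 4] == pytest.approx(3.0)  # root
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)

    def test_perfect_tree_gives_rho_one(self):
        h = _toy_hierarchy()
        D_true = hierarchy_cophenetic_matrix(h) * 2.5  # monotone transform
        assert cophenetic_correlation(h, D_true) == pytest.approx(1.0)

    def test_flat_hierarchy_undefined(self, caplog):
        h = ClusterHierarchy(cell_ids=[f"c{i}" for i in range(4)])
        h.root_compactness = 1.0
        with caplog.at_level("WARNING"):
            rho = cophenetic_correlation(h, np.ones((4, 4)) - np.eye(4))
        assert math.isnan(rho)

    def test_truth_distance_values(self):
        from msclust.simulate import GaussianSpec, build_correlation, truth_cophenetic

        spec = GaussianSpec(delta_rho=0.25)  # rho_in 0.5, rho_out 0.25
        _, truth = build_correlation(spec)
        D = truth_cophenetic(truth, spec)
        i, j = 0, 1  # same seed cluster
        assert D[i, j] == pytest.approx(math.sqrt(2 * (1 - 0.5)))
        k = 60  # same outer, different seed
        assert truth.outer_labels[k] == truth.outer_labels[i]
        assert D[i, k] == pytest.approx(math.sqrt(2 * (1 - 0.25)))
        far = 1049 if len(D) > 1000 else len(D) - 1
        assert truth.outer_labels[far] != truth.outer_labels[i]
        assert D[i, far] == pytest.approx(math.sqrt(2))


class TestLayerDetection:
    def test_verbatim_clusters_all_detected(self):
        inner = ClusterSet({"a": {"1", "2"}, "b": {"3", "4"}}, set("12345"))
        outer = ClusterSet({"o": {"1", "2", "3", "4"}}, set("12345"))
        res = ClusterSet(
            {"x": {"1", "2"}, "y": {"3", "4"}, "z": {"1", "2", "3", "4"}}, set("12345")
        )
        det = layer_detection(res, inner, outer)
        assert det["inner"]["detected"] == 2
        assert det["outer"]["detected"] == 1

    def test_partial_overlap_below_threshold(self):
        truth = ClusterSet({"t": {str(i) for i in range(50)}}, {str(i) for i in range(50)})
        res = ClusterSet({"r": {str(i) for i in range(38)}}, {str(i) for i in range(50)})
        det = layer_detection(res, truth, truth)
        assert det["inner"]["detected"] == 0  # JI = 38/50 = 0.76 < 0.8

    def test_empty_result_detects_nothing(self):
        truth = ClusterSet({"t": {"1", "2"}}, {"1", "2"})
        res = ClusterSet({}, {"1", "2"})
        det = layer_detection(res, truth, truth)
        assert det["inner"]["detected"] == 0


class TestNetworkStats:
    def test_sparsity_ratio(self):
        rng = np.random.default_rng(0)
        iu, ju = np.triu_indices(10, 1)
        sel = rng.choice(len(iu), 24, replace=False)
        g = graph_from_edges(10, list(zip(iu[sel], ju[sel])))
        assert network_stats(g).c_s == pytest.approx(2.4)

    def test_within_between_ratio(self):
        edges = clique_edges(range(5)) + clique_edges(range(5, 10))[:5] + [
            (0, 5), (1, 6), (2, 7), (3, 8), (4, 9)
        ]
        g = graph_from_edges(10, edges)
        stats = network_stats(g, np.repeat([0, 1], 5))
        assert stats.cluster_ratios[0] == pytest.approx(10 / 5)

    def test_isolated_clusters_get_inf(self):
        g = graph_from_edges(6, clique_edges(range(3)) + clique_edges(range(3, 6)))
        stats = network_stats(g, np.repeat([0, 1], 3))
        assert stats.cluster_ratios[0] == math.inf
        assert stats.cluster_ratios[1] == math.inf


def _bh_reference(pvals):
    """Step-up Benjamini-Hochberg adjusted p-values, written independently."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * n / (rank_idx + 1))
        adj[i] = val
        prev = val
    return adj


class TestFETEnrichment:
    def test_exclusive_cluster_strongly_enriched(self):
        counts = pd.DataFrame(
            {"s1": [10, 0], "s2": [0, 90]}, index=["c1", "c2"]
        )
        labels, res = fet_enrichment(counts, {"s1": "disease", "s2": "control"})
        p = res[(res.cluster == "c1") & (res["sample"] == "s1")]["p"].iloc[0]
        assert p < 1e-10
        assert labels["c1"] == ["disease"]

    def test_proportional_composition_not_enriched(self):
        counts = pd.DataFrame(
            {"s1": [20, 40], "s2": [10, 20]}, index=["c1", "c2"]
        )
        labels, res = fet_enrichment(counts, {"s1": "a", "s2": "b"})
        assert all(v == [] for v in labels.values())

    def test_half_of_condition_samples_suffices(self):
        counts = pd.DataFrame(
            {"s1": [30, 0], "s2": [5, 35], "s3": [0, 40]},
            index=["c1", "c2"],
        )
        labels, res = fet_enrichment(
            counts, {"s1": "disease", "s2": "disease", "s3": "control"}
        )
        assert "disease" in labels["c1"]

    def test_bh_matches_independent_stepup(self):
        rng = np.random.default_rng(5)
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(3, 40))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], _bh_reference(p), atol=1e-12
            )

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"s1": [-1, 2]}, index=["c1", "c2"])
        with pytest.raises(ValueError):
            fet_enrichment(counts, {"s1": "a"})
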