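"""Gap statistic, PAM, consensus composition, and cluster validation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from jawmorph.clustering import (
    ClusterSolution,
    cluster_once,
    consensus_cluster,
    gap_statistic,
    pam,
    subcluster,
    validate_clusters,
    variation_of_information,
)


def blobs(centers, n_per, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, c in enumerate(centers):
        X.append(rng.normal(c, sd, size=(n_per, len(c))))
        y += [i] * n_per
    return np.vstack(X), np.asarray(y)


class TestGapStatistic:
    def test_two_blobs_select_k2(self):
        X, _ = blobs([[0, 0], [10, 0]], 25, seed=1)
        g = gap_statistic(X, "kmeans", k_range=range(2, 6), B=50, seed=1,
                          restarts=5)
        assert g.selected_k == 2

    def test_result_invariants_and_defaults(self):
        X, _ = blobs([[0, 0], [8, 0], [0, 8]], 15, seed=2)
        g = gap_statistic(X, "hierarchical", k_range=range(2, 6), B=30, seed=0)
        assert len(g.gap) == len(g.se) == len(g.k_values)
        assert g.selected_k in g.k_values
        # printed defaults of the method: K in 2..10, 2000 reference cycles
        import inspect

        sig = inspect.signature(gap_statistic)
        assert tuple(sig.parameters["k_range"].default) == tuple(range(2, 11))
        assert sig.parameters["B"].default == 2000

    def test_small_b_warns(self):
        X, _ = blobs([[0, 0], [10, 0]], 10, seed=3)
        with pytest.warns(UserWarning, match="very small"):
            gap_statistic(X, "kmeans", k_range=range(2, 4), B=5, seed=0,
                          restarts=2)

    def test_k_range_validation(self):
        X, _ = blobs([[0, 0]], 5, seed=0)
        with pytest.raises(ValueError):
            gap_statistic(X, "kmeans", k_range=range(2, 12), B=20)


class TestPam:
    def test_recovers_blobs_and_matches_kmeans_partition(self):
        X, y = blobs([[0, 0], [10, 0], [0, 10]], 20, seed=4)
        labels, cost = pam(X, 3)
        assert adjusted_rand_score(y, labels) == 1.0
        km = cluster_once(X, 3, "kmeans", seed=0, restarts=10)
        assert adjusted_rand_score(labels, km) == 1.0

    def test_objective_is_total_distance_to_medoids(self):
        X, _ = blobs([[0, 0], [6, 0]], 10, seed=5)
        labels, cost = pam(X, 2)
        # recompute with the labelled medoids
        best = np.inf
        # cost must not exceed assigning everything to any two points
        for i in range(len(X)):
            for j in range(i + 1, len(X)):
                D = np.sqrt(((X[:, None] - X[[i, j]][None]) ** 2).sum(-1))
                best = min(best, D.min(axis=1).sum())
        assert cost == pytest.approx(best, rel=1e-9)


class TestConsensus:
    def test_unanimous_partitions_reproduced(self):
        X, y = blobs([[0, 0], [12, 0], [0, 12]], 15, seed=6)
        cc = consensus_cluster(X, k_range=range(2, 6), B=30, seed=0, restarts=5)
        assert cc.agreement_rate == 1.0
        assert len(cc.group_members()) == 3
        arr = [cc.labels[t] for t in cc.taxa]
        assert adjusted_rand_score(y, arr) == 1.0
        # coassignment is symmetric with unit diagonal, values in {0,1/3,2/3,1}
        assert np.allclose(cc.coassignment, cc.coassignment.T)
        assert np.allclose(np.diag(cc.coassignment), 1.0)
        vals = np.unique(np.round(cc.coassignment * 3))
        assert set(vals).issubset({0.0, 1.0, 2.0, 3.0})

    def test_two_of_three_majority_joins_component(self):
        """Hand-built coassignment: a taxon placed with group A by 2 of 3
        algorithms joins A's component."""
        from jawmorph.clustering import ConsensusClassification

        taxa = ["a1", "a2", "a3", "x", "b1", "b2", "b3"]
        # solutions: algorithms 1-2 put x with the a's, algorithm 3 with b's
        l1 = {"a1": 0, "a2": 0, "a3": 0, "x": 0, "b1": 1, "b2": 1, "b3": 1}
        l3 = {"a1": 0, "a2": 0, "a3": 0, "x": 1, "b1": 1, "b2": 1, "b3": 1}
        co = np.zeros((7, 7))
        for labs in (l1, l1, l3):
            arr = np.array([labs[t] for t in taxa])
            co += (arr[:, None] == arr[None, :]).astype(float)
        co /= 3
        adj = co >= 2 / 3 - 1e-12
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n_comp, comp = connected_components(csr_matrix(adj), directed=False)
        assert n_comp == 2
        assert comp[taxa.index("x")] == comp[taxa.index("a1")]

    def test_label_permutation_invariance(self):
        X, _ = blobs([[0, 0], [12, 0]], 12, seed=7)
        cc1 = consensus_cluster(X, k_range=range(2, 5), B=20, seed=3, restarts=5)
        # relabelling within an algorithm's solution must not change groups
        sol = cc1.per_algorithm[0]
        remapped = {t: 1 - l for t, l in sol.labels.items()}
        arr1 = np.array([sol.labels[t] for t in cc1.taxa])
        arr2 = np.array([remapped[t] for t in cc1.taxa])
        co1 = (arr1[:, None] == arr1[None, :])
        co2 = (arr2[:, None] == arr2[None, :])
        assert np.array_equal(co1, co2)

    def test_identical_rows_rejected(self):
        with pytest.raises(ValueError):
            consensus_cluster(np.ones((10, 3)), B=20, seed=0)

    def test_determinism(self):
        X, _ = blobs([[0, 0], [9, 0]], 15, seed=8)
        a = consensus_cluster(X, k_range=range(2, 5), B=20, seed=5, restarts=5)
        b = consensus_cluster(X, k_range=range(2, 5), B=20, seed=5, restarts=5)
        assert a.labels == b.labels
        assert np.array_equal(a.coassignment, b.coassignment)


class TestSubcluster:
    def test_nested_structure_recovered(self):
        rng = np.random.default_rng(9)
        centers, sub_truth, X = [], [], []
        # 3 parents, each two nested blobs at 6 sd
        for g in range(3):
            base = np.zeros(4)
            base[g] = 30.0
            for s in range(2):
                off = np.zeros(4)
                off[3] = 6.0 * s
                X.append(rng.normal(base + off, 1.0, size=(12, 4)))
                sub_truth += [f"{g}.{s}"] * 12
        X = np.vstack(X)
        taxa = [f"t{i}" for i in range(len(X))]
        parent = consensus_cluster(X, taxa=taxa, k_range=range(2, 6), B=30,
                                   seed=1, restarts=5)
        child = subcluster(X, parent, k_range=range(2, 6), B=30, seed=2,
                           restarts=5)
        arr = [child.labels[t] for t in taxa]
        n_sub = len(child.group_members())
        assert 5 <= n_sub <= 7
        assert adjusted_rand_score(sub_truth, arr) > 0.8

    def test_small_groups_pass_through(self):
        X = np.vstack([np.zeros((3, 2)), np.full((10, 2), 8.0)])
        X = X + np.random.default_rng(1).normal(0, 0.5, X.shape)
        taxa = [f"t{i}" for i in range(13)]
        parent = {t: ("A" if i < 3 else "B") for i, t in enumerate(taxa)}
        child = subcluster(X, parent, k_range=range(2, 4), B=20, seed=0,
                           restarts=3)
        assert {child.labels[t] for t in taxa[:3]} == {"A.1"}

    def test_unknown_parent_label_structure_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError):
            subcluster(X, {"t1": "A"}, B=20)  # labels don't cover rows


class TestValidation:
    def test_separated_blobs_high_silhouette(self):
        X, y = blobs([[0, 0], [10, 0]], 20, seed=10)
        labels = {f"t{i}": int(v) for i, v in enumerate(y)}
        ref = dict(labels)
        taxa = list(labels)
        rep = validate_clusters(labels, X, ref)
        assert rep["silhouette_mean"] > 0.7
        assert rep["adjusted_rand"] == 1.0
        assert rep["variation_of_information"] == pytest.approx(0.0, abs=1e-12)

    def test_random_labels_near_zero_ari(self):
        rng = np.random.default_rng(11)
        X, y = blobs([[0, 0], [10, 0]], 25, seed=11)
        aris = []
        for _ in range(100):
            perm = rng.permutation(y)
            labels = {f"t{i}": int(v) for i, v in enumerate(perm)}
            ref = {f"t{i}": int(v) for i, v in enumerate(y)}
            aris.append(validate_clusters(labels, X, ref)["adjusted_rand"])
        assert abs(np.mean(aris)) < 0.05

    def test_mismatched_taxon_sets_rejected(self):
        X, y = blobs([[0, 0], [5, 0]], 5, seed=0)
        labels = {f"t{i}": int(v) for i, v in enumerate(y)}
        with pytest.raises(ValueError):
            validate_clusters(labels, X, {"other": 1})

    def test_variation_of_information_properties(self):
        a = [0, 0, 1, 1, 2, 2]
        assert variation_of_information(a, a) == pytest.approx(0.0, abs=1e-12)
        b = [0, 1, 0, 1, 0, 1]
        vi = variation_of_information(a, b)
        assert vi > 0
        assert vi == pytest.approx(variation_of_information(b, a))
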