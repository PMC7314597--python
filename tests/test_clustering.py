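"""K-means subgrouping of map nodes, allocation, silhouette, stability."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from cogmap.clustering import (
    _stability_partition,
    allocate_to_clusters,
    kmeans_nodes,
    profile_summary,
    silhouette_scan,
    stability_analysis,
)
from cogmap.datasets import CohortSpec, Profile, separated_baseline_spec, simulate_baseline_cohort
from cogmap.som import SOMConfig, batch_train, best_matching_unit
from conftest import make_table, model_from_weights, random_table


def brute_best_two_partition(points):
    """Exhaustive minimum within-cluster-SS 2-partition of <= ~12 points."""
    n = len(points)
    best, best_ss = None, np.inf
    for size_a in range(1, n // 2 + 1):
        for combo in itertools.combinations(range(n), size_a):
            a = points[list(combo)]
            b = points[[i for i in range(n) if i not in combo]]
            ss = ((a - a.mean(0)) ** 2).sum() + ((b - b.mean(0)) ** 2).sum()
            if ss < best_ss - 1e-12:
                best_ss, best = ss, set(combo)
    return best, best_ss


class TestKmeansNodes:
    def test_k1_centroid_is_mean_node_weight(self, small_trained_model):
        model, _ = small_trained_model
        sol = kmeans_nodes(model, k=1, n_restarts=5, seed=0)
        assert np.all(sol.node_labels == 1)
        np.testing.assert_allclose(sol.centroids[0], model.weights.mean(axis=0))

    def test_six_nodes_match_exhaustive_optimum(self, rng):
        for _ in range(10):
            weights = rng.normal(size=(6, 4))
            model = model_from_weights(weights)
            sol = kmeans_nodes(model, k=2, n_restarts=30, seed=1)
            brute_set, brute_ss = brute_best_two_partition(weights)
            ours = set(np.flatnonzero(sol.node_labels == sol.node_labels[min(brute_set)]))
            assert sol.inertia == pytest.approx(brute_ss, rel=1e-9)
            assert ours in (brute_set, set(range(6)) - brute_set)

    def test_labels_ordered_by_descending_grand_mean(self, rng):
        blobs = np.concatenate(
            [rng.normal(m, 0.5, size=(8, 4)) for m in (40.0, 120.0, 80.0, 160.0)]
        )
        model = model_from_weights(blobs)
        sol = kmeans_nodes(model, k=4, n_restarts=30, seed=2)
        grand = sol.centroids.mean(axis=1)
        assert np.all(np.diff(grand) <= 0)
        assert sol.node_labels[-1] == 1  # the 160-mean blob is cluster 1

    def test_k_larger_than_nodes_rejected(self, small_trained_model):
        model, _ = small_trained_model
        with pytest.raises(ValueError):
            kmeans_nodes(model, k=model.n_nodes + 1)

    def test_deterministic_given_seed(self, small_trained_model):
        model, _ = small_trained_model
        a = kmeans_nodes(model, k=4, seed=9)
        b = kmeans_nodes(model, k=4, seed=9)
        assert np.array_equal(a.node_labels, b.node_labels)
        assert a.inertia == b.inertia

    def test_inertia_beats_random_partitions(self, small_trained_model, rng):
        model, _ = small_trained_model
        sol = kmeans_nodes(model, k=3, seed=0)
        for _ in range(20):
            labels = rng.integers(0, 3, size=model.n_nodes)
            ss = sum(
                ((model.weights[labels == c] - model.weights[labels == c].mean(0)) ** 2).sum()
                for c in range(3)
                if (labels == c).any()
            )
            assert sol.inertia <= ss + 1e-9


class TestAllocation:
    def test_participant_on_node_gets_that_nodes_cluster(self, small_trained_model):
        model, _ = small_trained_model
        sol = kmeans_nodes(model, k=3, seed=0)
        table = make_table(model.weights[[2, 9]])
        alloc = allocate_to_clusters(model, sol, table)
        assert list(alloc["bmu"]) == [2, 9]
        assert list(alloc["cluster"]) == [sol.node_labels[2], sol.node_labels[9]]

    def test_identical_participants_share_a_cluster(self, small_trained_model):
        model, _ = small_trained_model
        sol = kmeans_nodes(model, k=4, seed=0)
        table = make_table(np.tile([100.0, 90.0, 95.0, 105.0], (6, 1)))
        alloc = allocate_to_clusters(model, sol, table)
        assert alloc["cluster"].nunique() == 1

    def test_matches_bmu_lookup_composition(self, small_trained_model, rng):
        model, _ = small_trained_model
        sol = kmeans_nodes(model, k=4, seed=3)
        table = random_table(rng, n=15)
        alloc = allocate_to_clusters(model, sol, table)
        for i, row in enumerate(table.scores):
            bmu = best_matching_unit(row, model.weights)
            assert alloc["bmu"][i] == bmu
            assert alloc["cluster"][i] == sol.node_labels[bmu]


class TestSilhouette:
    def test_two_far_blobs_score_high_at_k2(self, rng):
        blobs = np.concatenate(
            [rng.normal(0.0, 0.5, size=(8, 4)), rng.normal(100.0, 0.5, size=(8, 4))]
        )
        model = model_from_weights(blobs)
        scores = silhouette_scan(model, [2], seed=0)
        assert scores[2] > 0.9

    def test_all_singletons_score_zero_by_convention(self, small_trained_model):
        model, _ = small_trained_model
        scores = silhouette_scan(model, [model.n_nodes], seed=0)
        assert scores[model.n_nodes] == 0.0

    def test_k_below_two_excluded_with_warning(self, small_trained_model):
        model, _ = small_trained_model
        with pytest.warns(UserWarning, match="silhouette"):
            scores = silhouette_scan(model, [1, 2], seed=0)
        assert 1 not in scores and 2 in scores

    def test_four_point_hand_example(self):
        # two pairs on a line: (0, 1) and (10, 11); k=2 splits the pairs.
        # outer points (0, 11): a=1, b=(10+11)/2=10.5 -> s=9.5/10.5
        # inner points (1, 10): a=1, b=(9+10)/2=9.5  -> s=8.5/9.5
        pts = np.array([[0.0], [1.0], [10.0], [11.0]])
        pts = np.column_stack([pts, np.zeros((4, 3))])
        model = model_from_weights(pts)
        scores = silhouette_scan(model, [2], seed=0)
        expected = (2 * (9.5 / 10.5) + 2 * (8.5 / 9.5)) / 4
        assert scores[2] == pytest.approx(expected)


class TestStability:
    def test_same_rep_seed_reproduces_partition_exactly(self, rng):
        table = simulate_baseline_cohort(separated_baseline_spec(120, seed=5))
        config = SOMConfig(grid_rows=4, grid_cols=4, ordering_steps=4, fine_tune_steps=1)
        a = _stability_partition(table, config, 4, rep_seed=77, n_restarts=10)
        b = _stability_partition(table, config, 4, rep_seed=77, n_restarts=10)
        assert adjusted_rand_score(a, b) == 1.0

    def test_separated_profiles_are_stable(self):
        table = simulate_baseline_cohort(separated_baseline_spec(200, seed=8))
        config = SOMConfig(ordering_steps=5, fine_tune_steps=1)
        report = stability_analysis(table, config, k=4, n_reps=8, seed=1, n_restarts=10)
        assert report.mean_agreement >= 0.9

    def test_unstructured_cohort_less_stable_than_separated(self):
        sep = simulate_baseline_cohort(separated_baseline_spec(200, seed=8))
        iso = simulate_baseline_cohort(
            CohortSpec(
                n_participants=200,
                profiles=(
                    Profile(centroid=[100.0] * 4, covariance=np.eye(4) * 225.0, weight=1.0),
                ),
                seed=8,
            )
        )
        config = SOMConfig(ordering_steps=5, fine_tune_steps=1)
        rep_sep = stability_analysis(sep, config, k=4, n_reps=6, seed=2, n_restarts=10)
        rep_iso = stability_analysis(iso, config, k=4, n_reps=6, seed=2, n_restarts=10)
        assert rep_iso.mean_agreement < rep_sep.mean_agreement

    def test_degenerate_data_rejected(self):
        table = make_table(np.full((20, 4), 100.0))
        with pytest.raises(ValueError, match="degenerate"):
            stability_analysis(table, SOMConfig(), k=2, n_reps=2, seed=0)


class TestProfileSummary:
    def test_single_cluster_reproduces_column_means(self, small_trained_model, rng):
        model, _ = small_trained_model
        sol = kmeans_nodes(model, k=1, seed=0)
        table = random_table(rng, n=12)
        alloc = allocate_to_clusters(model, sol, table)
        summary = profile_summary(alloc, table)
        for j, task in enumerate(table.task_names):
            row = summary[(summary["cluster"] == 1) & (summary["task"] == task)].iloc[0]
            assert row["mean"] == pytest.approx(table.scores[:, j].mean())
            assert row["ci_upper"] - row["ci_lower"] == pytest.approx(2 * 1.96 * row["se"])

    def test_two_cluster_hand_fixture(self, small_trained_model):
        model, _ = small_trained_model
        import pandas as pd

        table = make_table(
            np.array([[10.0, 0, 0, 0], [14.0, 0, 0, 0], [100.0, 0, 0, 0], [104.0, 0, 0, 0]])
        )
        alloc = pd.DataFrame(
            {
                "participant_id": list(table.ids),
                "bmu": [0, 0, 1, 1],
                "cluster": [1, 1, 2, 2],
            }
        )
        summary = profile_summary(alloc, table)
        row = summary[(summary["cluster"] == 1) & (summary["task"] == "forward_digit")].iloc[0]
        assert row["mean"] == pytest.approx(12.0)
        # SD of (10, 14) = sqrt(8); SE = sqrt(8)/sqrt(2) = 2
        assert row["se"] == pytest.approx(2.0)
        assert row["ci_lower"] == pytest.approx(12.0 - 1.96 * 2.0)
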