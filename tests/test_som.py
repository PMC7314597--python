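"""Batch SOM engine: schedule, initialization, training, fit measures."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogmap.datasets import CohortSpec, Profile
from cogmap.datasets import simulate_baseline_cohort
from cogmap.som import (
    SOMConfig,
    SOMModel,
    batch_cycle,
    batch_train,
    best_matching_unit,
    component_planes,
    grid_distances,
    initialize_weights,
    neighbourhood_size,
    quantization_error,
)
from conftest import make_table, model_from_weights, random_table


# --- independent brute-force oracles (explicit loops) ----------------------


def brute_bmu(x, weights):
    best, best_d = 0, np.inf
    for i in range(weights.shape[0]):
        d = ((x - weights[i]) ** 2).sum()
        if d < best_d:
            best, best_d = i, d
    return best


def brute_batch_cycle(weights, x, node_dist, radius):
    """Literal buffer description: sums over neighbourhood sets, then means."""
    n_nodes = weights.shape[0]
    bmus = [brute_bmu(row, weights) for row in x]
    new = weights.copy()
    for i in range(n_nodes):
        buffer = [x[t] for t in range(len(x)) if node_dist[i, bmus[t]] <= radius]
        if buffer:
            new[i] = np.sum(buffer, axis=0) / len(buffer)
    return new


def brute_quantization_error(weights, x):
    total = 0.0
    for row in x:
        total += np.sqrt(((row - weights[brute_bmu(row, weights)]) ** 2).sum())
    return total / len(x)


class TestNeighbourhoodSchedule:
    @pytest.mark.parametrize(
        "t,ins,n,expected", [(0, 2, 10, 3.0), (10, 2, 10, 1.0), (10, 7.5, 10, 1.0), (5, 2, 10, 2.0)]
    )
    def test_schedule_values(self, t, ins, n, expected):
        assert neighbourhood_size(t, ins, n) == pytest.approx(expected)

    @pytest.mark.parametrize("t", [-1, 11])
    def test_out_of_range_step_rejected(self, t):
        with pytest.raises(ValueError):
            neighbourhood_size(t, 2, 10)


class TestInitialization:
    def test_planar_data_stays_in_pc_plane(self, rng):
        # data constructed exactly in a 2-D plane of 4-space
        basis = np.linalg.qr(rng.normal(size=(4, 2)))[0]
        coefs = rng.normal(0, 10, size=(30, 2))
        data = make_table(100.0 + coefs @ basis.T)
        w = initialize_weights(data, SOMConfig(grid_rows=4, grid_cols=4))
        centered = w - data.scores.mean(axis=0)
        residual = centered - centered @ basis @ basis.T
        assert np.abs(residual).max() < 1e-8

    def test_zero_variance_data_falls_back_to_mean(self):
        data = make_table(np.full((10, 4), 100.0))
        with pytest.warns(UserWarning, match="rank"):
            w = initialize_weights(data, SOMConfig())
        assert np.abs(w - 100.0).max() < 1e-2

    def test_corner_nodes_match_eigendecomposition(self, rng):
        data = random_table(rng, n=80)
        config = SOMConfig(grid_rows=8, grid_cols=8)
        w = initialize_weights(data, config)
        x = data.scores
        mean = x.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(np.cov(x, rowvar=False))
        order = np.argsort(eigvals)[::-1]
        l1, l2 = eigvals[order[:2]]
        u1, u2 = eigvecs[:, order[0]], eigvecs[:, order[1]]
        corner = w[0]  # node (0, 0): a_r = b_c = -2
        # sign of eigenvectors is a convention; test the two sign choices
        candidates = [
            mean - 2 * np.sqrt(l1) * s1 * u1 - 2 * np.sqrt(l2) * s2 * u2
            for s1 in (1, -1)
            for s2 in (1, -1)
        ]
        assert min(np.abs(corner - c).max() for c in candidates) < 1e-8


class TestBMU:
    def test_exact_node_match_returns_that_node(self, rng):
        weights = rng.normal(size=(16, 4))
        assert best_matching_unit(weights[7], weights) == 7

    def test_tie_broken_by_lowest_index(self):
        weights = np.array([[10.0, 10.0], [2.0, 0.0], [10.0, 10.0], [0.0, 2.0]])
        # nodes 1 and 3 equidistant from x; lower row-major index wins
        assert best_matching_unit(np.array([1.0, 1.0]), weights) == 1

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            best_matching_unit(np.zeros(3), rng.normal(size=(4, 4)))

    def test_matches_brute_force_scan(self, rng):
        for _ in range(30):
            weights = rng.normal(100, 15, size=(64, 4))
            x = rng.normal(100, 15, size=4)
            assert best_matching_unit(x, weights) == brute_bmu(x, weights)


class TestBatchTraining:
    def test_identical_rows_converge_to_zero_error(self):
        data = make_table(np.tile([95.0, 105.0, 90.0, 110.0], (20, 1)))
        with pytest.warns(UserWarning):  # rank-deficient init
            model = batch_train(data, SOMConfig(grid_rows=2, grid_cols=2))
        assert model.quantization_error == pytest.approx(0.0, abs=1e-9)

    def test_separated_points_captured_exactly_by_2x2_fine_tuning(self):
        # four well-separated points, each node initialized nearest a distinct
        # point; fine-tuning cycles (BMU-only buffers) pull each node exactly
        # onto its point
        pts = np.array(
            [[0.0, 0.0, 0, 0], [100, 0, 0, 0], [0, 100, 0, 0], [100, 100, 0, 0]], dtype=float
        )
        config = SOMConfig(grid_rows=2, grid_cols=2)
        node_dist = grid_distances(config)
        weights = pts + 3.0  # near, but not on, the points
        for _ in range(2):
            weights = batch_cycle(weights, pts, node_dist, 0.0)
        np.testing.assert_allclose(weights, pts, atol=1e-12)
        assert brute_quantization_error(weights, pts) == pytest.approx(0.0, abs=1e-12)

    def test_single_cycle_matches_brute_force(self, rng):
        config = SOMConfig(grid_rows=3, grid_cols=4, ordering_steps=4)
        node_dist = grid_distances(config)
        for _ in range(20):
            weights = rng.normal(100, 10, size=(12, 4))
            x = rng.normal(100, 15, size=(25, 4))
            radius = float(rng.choice([0.0, 1.0, 1.5, 2.0, 3.0]))
            ours = batch_cycle(weights, x, node_dist, radius)
            brute = brute_batch_cycle(weights, x, node_dist, radius)
            np.testing.assert_allclose(ours, brute, rtol=1e-10, atol=1e-10)

    def test_full_schedule_is_deterministic(self, rng):
        data = random_table(rng, n=50)
        config = SOMConfig(grid_rows=4, grid_cols=4)
        a = batch_train(data, config)
        b = batch_train(data, config)
        assert np.array_equal(a.weights, b.weights)
        assert a.quantization_error == b.quantization_error

    def test_training_reduces_quantization_error(self, rng):
        data = random_table(rng, n=100)
        config = SOMConfig(grid_rows=4, grid_cols=4)
        init = initialize_weights(data, config)
        model = batch_train(data, config)
        init_model = model_from_weights(init)
        assert model.quantization_error <= quantization_error(init_model, data)

    def test_empty_data_rejected(self):
        with pytest.raises(Exception):
            batch_train(make_table(np.empty((0, 4))), SOMConfig())

    def test_two_profiles_occupy_disjoint_regions(self):
        cov = np.eye(4) * 9.0
        spec = CohortSpec(
            n_participants=120,
            profiles=(
                Profile(centroid=[70.0] * 4, covariance=cov, weight=0.5),
                Profile(centroid=[130.0] * 4, covariance=cov, weight=0.5),
            ),
            seed=11,
        )
        table, labels = simulate_baseline_cohort(spec, return_labels=True)
        model = batch_train(table, SOMConfig())
        bmus = model.bmus(table.scores)
        assert not set(bmus[labels == 0]) & set(bmus[labels == 1])


class TestQuantizationError:
    def test_inputs_on_nodes_give_zero(self, rng):
        weights = rng.normal(size=(16, 4))
        model = model_from_weights(weights)
        data = make_table(weights[[3, 5, 9]])
        assert quantization_error(model, data) == pytest.approx(0.0)

    def test_single_input_gives_its_distance(self):
        weights = np.zeros((4, 4))
        weights[1:] = 1000.0
        model = model_from_weights(weights)
        data = make_table(np.array([[3.0, 4.0, 0.0, 0.0]]))
        assert quantization_error(model, data) == pytest.approx(5.0)

    def test_matches_direct_loop(self, rng):
        weights = rng.normal(100, 15, size=(16, 4))
        x = rng.normal(100, 15, size=(30, 4))
        model = model_from_weights(weights)
        assert quantization_error(model, make_table(x)) == pytest.approx(
            brute_quantization_error(weights, x), rel=1e-12
        )


class TestComponentPlanes:
    def test_planes_reassemble_weight_matrix(self, small_trained_model):
        model, _ = small_trained_model
        planes = component_planes(model)
        assert len(planes) == len(model.task_names)
        stacked = np.column_stack([p.values for p in planes])
        assert np.array_equal(stacked, model.weights)

    def test_hand_set_toy_weights(self):
        w = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0], [4.0, 40.0]])
        model = model_from_weights(w, task_names=("alpha", "beta"))
        planes = component_planes(model)
        assert planes[0].task_name == "alpha"
        assert np.array_equal(planes[0].values, [1.0, 2.0, 3.0, 4.0])
        assert np.array_equal(planes[1].values, [10.0, 20.0, 30.0, 40.0])


class TestSerialization:
    def test_json_roundtrip_is_bit_exact(self, tmp_path, small_trained_model):
        model, _ = small_trained_model
        path = tmp_path / "model.json"
        model.save(path)
        back = SOMModel.load(path)
        assert np.array_equal(back.weights, model.weights)
        assert back.config == model.config
        assert back.quantization_error == model.quantization_error
        assert back.task_names == model.task_names


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_cycles_preserve_finiteness_and_shape(seed):
    rng = np.random.default_rng(seed)
    config = SOMConfig(grid_rows=3, grid_cols=3, ordering_steps=3, fine_tune_steps=1)
    data = make_table(rng.normal(100, 15, size=(12, 4)))
    model = batch_train(data, config)
    assert model.weights.shape == (9, 4)
    assert np.all(np.isfinite(model.weights))
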