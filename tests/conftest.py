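import numpy as np
import pytest

from cogmap.datasets import DEFAULT_TASKS, ScoreTable
from cogmap.som import SOMConfig, SOMModel, batch_train, grid_coordinates


def make_table(scores, task_names=DEFAULT_TASKS, **kwargs) -> ScoreTable:
    scores = np.asarray(scores, dtype=float)
    ids = tuple(f"P{i}" for i in range(scores.shape[0]))
    return ScoreTable(ids=ids, scores=scores, task_names=task_names[: scores.shape[1]], **kwargs)


def random_table(rng, n=40, n_tasks=4) -> ScoreTable:
    return make_table(rng.normal(100, 15, size=(n, n_tasks)), task_names=DEFAULT_TASKS[:n_tasks])


def model_from_weights(weights, task_names=None) -> SOMModel:
    """Wrap an explicit weight matrix in a SOMModel (square-ish grid)."""
    weights = np.asarray(weights, dtype=float)
    n_nodes = weights.shape[0]
    rows = int(np.sqrt(n_nodes))
    while n_nodes % rows:
        rows -= 1
    config = SOMConfig(grid_rows=rows, grid_cols=n_nodes // rows)
    names = tuple(task_names) if task_names else DEFAULT_TASKS[: weights.shape[1]]
    return SOMModel(
        weights=weights,
        grid_coords=grid_coordinates(config),
        config=config,
        quantization_error=0.0,
        task_names=names,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_trained_model():
    """A 4x4 map trained on a small random cohort (shared across tests)."""
    rng = np.random.default_rng(7)
    table = make_table(rng.normal(100, 15, size=(60, 4)))
    config = SOMConfig(grid_rows=4, grid_cols=4, ordering_steps=5, fine_tune_steps=1)
    return batch_train(table, config), table
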