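"""Batch self-organizing map (SOM) engine.

A SOM projects multivariate profiles onto a two-dimensional lattice of
nodes; each node i carries a weight vector m_i living in the input space.
Training here is the classic batch scheme: every cycle, each input is
assigned to its Best Matching Unit (BMU, the node with the least Euclidean
distance), each node accumulates a buffer of the inputs whose BMU lies
within the current neighbourhood radius, and all node weights are replaced
concurrently by their buffer means.  The neighbourhood radius shrinks
linearly over an "ordering" phase,

    ND(t) = 1 + INS * (1 - t / n),

from 1 + INS down to 1 over n steps, after which a "fine-tuning" phase
updates each node from only the inputs for which it is the BMU.

Weights are initialized on the plane spanned by the first two principal
components of the training data (Kohonen's linear initialization), which
makes training fully deterministic given the data and configuration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np

from .datasets import ScoreTable

__all__ = [
    "SOMConfig",
    "SOMModel",
    "ComponentPlane",
    "neighbourhood_size",
    "initialize_weights",
    "best_matching_unit",
    "batch_train",
    "batch_cycle",
    "quantization_error",
    "component_planes",
]

logger = logging.getLogger(__name__)

TOPOLOGIES = ("rectangular", "hexagonal")
GRID_METRICS = ("chebyshev", "link")


@dataclass(frozen=True)
class SOMConfig:
    """Map geometry and training schedule.

    Defaults follow the reference analysis: an 8x8 (64-node) map, initial
    neighbourhood size 2, ten ordering steps and two fine-tuning steps, on a
    rectangular lattice with Chebyshev grid distance.
    """

    grid_rows: int = 8
    grid_cols: int = 8
    initial_neighbourhood: float = 2.0
    ordering_steps: int = 10
    fine_tune_steps: int = 2
    topology: str = "rectangular"
    grid_metric: str = "chebyshev"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1 or self.grid_rows * self.grid_cols < 4:
            raise ValueError("grid must contain at least 4 nodes")
        if self.initial_neighbourhood <= 0:
            raise ValueError("initial_neighbourhood must be positive")
        if self.ordering_steps < 1:
            raise ValueError("ordering_steps must be >= 1")
        if self.fine_tune_steps < 0:
            raise ValueError("fine_tune_steps must be nonnegative")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        if self.grid_metric not in GRID_METRICS:
            raise ValueError(f"grid_metric must be one of {GRID_METRICS}")

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols


def grid_coordinates(config: SOMConfig) -> np.ndarray:
    """Row-major (row, col) lattice coordinates, shape (n_nodes, 2)."""
    rows, cols = np.divmod(np.arange(config.n_nodes), config.grid_cols)
    return np.column_stack([rows, cols])


def grid_distances(config: SOMConfig) -> np.ndarray:
    """Pairwise node-to-node lattice distances, shape (n_nodes, n_nodes)."""
    coords = grid_coordinates(config)
    dr = np.abs(coords[:, None, 0] - coords[None, :, 0])
    dc = np.abs(coords[:, None, 1] - coords[None, :, 1])
    if config.topology == "hexagonal":
        # odd-r offset rows -> axial coordinates, then hex lattice distance
        r = coords[:, 0]
        q = coords[:, 1] - (r - (r & 1)) // 2
        dq = q[:, None] - q[None, :]
        drr = r[:, None] - r[None, :]
        return (np.abs(dq) + np.abs(drr) + np.abs(dq + drr)) / 2.0
    if config.grid_metric == "chebyshev":
        return np.maximum(dr, dc).astype(float)
    return (dr + dc).astype(float)  # "link": shortest 4-connected path


def neighbourhood_size(t: float, ins: float, n: int) -> float:
    """Linearly shrinking neighbourhood radius ND(t) = 1 + INS * (1 - t/n)."""
    if t < 0 or t > n:
        raise ValueError(f"step index t={t} outside [0, {n}]")
    return 1.0 + ins * (1.0 - t / n)


@dataclass(frozen=True)
class ComponentPlane:
    """One element of every node-weight vector: the map's view of one task."""

    task_name: str
    values: np.ndarray


@dataclass(frozen=True)
class SOMModel:
    """A trained map: node weights, lattice geometry and fit error."""

    weights: np.ndarray
    grid_coords: np.ndarray
    config: SOMConfig
    quantization_error: float
    task_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "task_names", tuple(self.task_names))
        if self.weights.shape[0] != self.config.n_nodes:
            raise ValueError("weight matrix rows must equal grid_rows * grid_cols")
        if self.weights.shape[1] != len(self.task_names):
            raise ValueError("weight matrix columns must match task_names")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def bmus(self, scores: np.ndarray) -> np.ndarray:
        """Best Matching Unit index for each row of ``scores``."""
        return _bmus(np.atleast_2d(np.asarray(scores, dtype=float)), self.weights)

    def save(self, path: str | Path) -> None:
        doc = {
            "config": asdict(self.config),
            "task_names": list(self.task_names),
            "grid_shape": [self.config.grid_rows, self.config.grid_cols],
            "quantization_error": self.quantization_error,
            "weights": [[float(v) for v in row] for row in self.weights],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SOMModel":
        doc = json.loads(Path(path).read_text())
        config = SOMConfig(**doc["config"])
        return cls(
            weights=np.array(doc["weights"], dtype=float),
            grid_coords=grid_coordinates(config),
            config=config,
            quantization_error=float(doc["quantization_error"]),
            task_names=tuple(doc["task_names"]),
        )


def _sq_dists(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, rows of x against rows of weights."""
    return ((x[:, None, :] - weights[None, :, :]) ** 2).sum(axis=-1)


def _bmus(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    # np.argmin returns the first (lowest row-major) index on ties
    return np.argmin(_sq_dists(x, weights), axis=1)


def best_matching_unit(x: np.ndarray, weights: np.ndarray) -> int:
    """Index of the node nearest to ``x`` (ties -> lowest row-major index)."""
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if x.shape != (weights.shape[1],):
        raise ValueError(f"input dimension {x.shape} does not match weights {weights.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("input vector must be finite")
    return int(_bmus(x[None, :], weights)[0])


def initialize_weights(data: ScoreTable, config: SOMConfig) -> np.ndarray:
    """Linear (PCA) initialization of the node-weight matrix.

    Node (r, c) starts at ``mean + a_r*sqrt(l1)*u1 + b_c*sqrt(l2)*u2`` where
    (l_i, u_i) are the two leading eigenpairs of the data covariance and
    a_r, b_c are linearly spaced over [-2, 2] along the lattice rows and
    columns.  If the data have rank < 2 the initialization falls back to the
    mean plus a small seeded jitter (magnitude 1e-3 of each task's SD).
    """
    x = data.scores
    if x.shape[0] < 3:
        raise ValueError("PCA initialization requires at least 3 rows")
    if x.shape[1] < 2:
        raise ValueError("PCA initialization requires at least 2 tasks")
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(eigvals[0], 1.0)
    if eigvals[1] <= tol:  # rank-deficient: degenerate second direction
        msg = "training data rank < 2; falling back to mean + seeded jitter"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
        rng = np.random.default_rng(config.seed)
        sd = x.std(axis=0, ddof=0)
        jitter = rng.normal(0.0, 1.0, size=(config.n_nodes, x.shape[1])) * (1e-3 * sd)
        return mean[None, :] + jitter
    # deterministic eigenvector sign: largest-|.| component positive
    for j in range(2):
        lead = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[lead, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    a = np.linspace(-2.0, 2.0, config.grid_rows) if config.grid_rows > 1 else np.zeros(1)
    b = np.linspace(-2.0, 2.0, config.grid_cols) if config.grid_cols > 1 else np.zeros(1)
    coords = grid_coordinates(config)
    along_rows = a[coords[:, 0], None] * (np.sqrt(eigvals[0]) * eigvecs[:, 0])[None, :]
    along_cols = b[coords[:, 1], None] * (np.sqrt(eigvals[1]) * eigvecs[:, 1])[None, :]
    return mean[None, :] + along_rows + along_cols


def batch_cycle(
    weights: np.ndarray, x: np.ndarray, node_distances: np.ndarray, radius: float
) -> np.ndarray:
    """One concurrent batch update of all node weights.

    Each input joins the buffer of every node within lattice ``radius`` of
    its BMU; each node with a nonempty buffer is replaced by its buffer mean,
    nodes with empty buffers keep their previous weights.
    """
    n_nodes, n_dim = weights.shape
    bmu = _bmus(x, weights)
    sums = np.zeros((n_nodes, n_dim))
    np.add.at(sums, bmu, x)
    counts = np.bincount(bmu, minlength=n_nodes).astype(float)
    member = node_distances <= radius  # member[i, j]: node j in node i's neighbourhood
    num = member @ sums
    den = member @ counts
    updated = weights.copy()
    nonempty = den > 0
    updated[nonempty] = num[nonempty] / den[nonempty, None]
    return updated


def batch_train(data: ScoreTable, config: SOMConfig) -> SOMModel:
    """Train a SOM with the batch algorithm.

    Runs ``ordering_steps`` cycles with the shrinking neighbourhood ND(t)
    evaluated at t = 1..n (the final ordering cycle uses radius exactly 1),
    then ``fine_tune_steps`` cycles restricted to the BMU alone.  Fully
    deterministic given the data and configuration.
    """
    if data.n_participants == 0:
        raise ValueError("cannot train on an empty table")
    x = data.scores
    if not np.all(np.isfinite(x)):
        raise ValueError("training data contain non-finite scores")
    weights = initialize_weights(data, config)
    node_dist = grid_distances(config)
    n = config.ordering_steps
    for t in range(1, n + 1):
        radius = neighbourhood_size(t, config.initial_neighbourhood, n)
        weights = batch_cycle(weights, x, node_dist, radius)
    for _ in range(config.fine_tune_steps):
        weights = batch_cycle(weights, x, node_dist, 0.0)  # {BMU only}
    model = SOMModel(
        weights=weights,
        grid_coords=grid_coordinates(config),
        config=config,
        quantization_error=0.0,
        task_names=data.task_names,
    )
    qe = quantization_error(model, data)
    return SOMModel(
        weights=weights,
        grid_coords=grid_coordinates(config),
        config=config,
        quantization_error=qe,
        task_names=data.task_names,
    )


def quantization_error(model: SOMModel, data: ScoreTable) -> float:
    """Mean Euclidean distance between inputs and their BMUs."""
    if data.n_participants == 0:
        raise ValueError("quantization error undefined for empty data")
    if data.n_tasks != model.weights.shape[1]:
        raise ValueError("data dimensionality does not match the model")
    d2 = _sq_dists(data.scores, model.weights)
    return float(np.sqrt(d2.min(axis=1)).mean())


def component_planes(model: SOMModel) -> list[ComponentPlane]:
    """One plane per task: column k of the weight matrix."""
    return [
        ComponentPlane(task_name=name, values=model.weights[:, k].copy())
        for k, name in enumerate(model.task_names)
    ]
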