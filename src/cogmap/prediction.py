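"""Map validation by held-out prediction against permutation nulls.

A trained map predicts a participant's score on one task from their scores
on the remaining tasks: the K nodes nearest in the observed-task subspace
vote for the target element, weighted by inverse distance.  Leave-N-out
cross-validation repeats this over many random splits and compares the mean
absolute prediction error against a null distribution built by shuffling
the predicted scores; a permutation test on pooled error sets compares
predictability across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .datasets import ScoreTable
from .som import SOMConfig, SOMModel, batch_train, _sq_dists

__all__ = [
    "PermutationResult",
    "CVReport",
    "GeneralizationReport",
    "knn_predict",
    "predict_table",
    "permutation_p",
    "cross_validate",
    "generalization_errors",
    "compare_error_sets",
]

WEIGHTINGS = ("inverse", "uniform", "inverse_squared")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic, its permutation null and an add-one p-value."""

    observed_statistic: float
    null_values: np.ndarray
    n_resamples: int
    p_value: float
    seed: int


@dataclass(frozen=True)
class CVReport:
    """Leave-N-out cross-validation summary.

    ``per_task_mae``/``per_task_p`` aggregate over all repetitions (the p
    compares the mean MAE against the null pooled across repetitions);
    ``per_rep_mae``/``per_rep_p`` retain each repetition's own error and
    within-repetition permutation p.
    """

    task_names: tuple[str, ...]
    per_task_mae: np.ndarray
    per_task_p: np.ndarray
    per_rep_mae: np.ndarray  # (n_reps, n_tasks)
    per_rep_p: np.ndarray  # (n_reps, n_tasks)
    n_reps: int
    holdout_fraction: float
    k_neighbours: int
    shuffles_per_rep: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        doc = {
            "task_names": list(self.task_names),
            "per_task_mae": [float(v) for v in self.per_task_mae],
            "per_task_p": [float(v) for v in self.per_task_p],
            "n_reps": self.n_reps,
            "holdout_fraction": self.holdout_fraction,
            "k_neighbours": self.k_neighbours,
            "shuffles_per_rep": self.shuffles_per_rep,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    def errors_frame(self) -> pd.DataFrame:
        """Long-format per-repetition per-task errors."""
        reps, tasks = np.meshgrid(
            np.arange(self.n_reps), np.arange(len(self.task_names)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "rep": reps.ravel(),
                "task": [self.task_names[t] for t in tasks.ravel()],
                "mae": self.per_rep_mae.ravel(),
                "p": self.per_rep_p.ravel(),
            }
        )


@dataclass(frozen=True)
class GeneralizationReport:
    """Per-task errors of a fixed map on an external cohort."""

    task_names: tuple[str, ...]
    per_task_mae: np.ndarray
    per_task_result: tuple[PermutationResult, ...]


def _subspace_prediction(
    weights: np.ndarray,
    observed: np.ndarray,
    obs_idx: np.ndarray,
    target_idx: int,
    k: int,
    weighting: str,
) -> np.ndarray:
    """Vectorized KNN-node prediction for many rows at once."""
    d2 = _sq_dists(observed, weights[:, obs_idx])
    # stable ordering: ties broken by lowest node index
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    dk = np.sqrt(np.take_along_axis(d2, order, axis=1))
    targets = weights[:, target_idx][order]
    preds = np.empty(observed.shape[0])
    zero_rows = (dk == 0).any(axis=1)
    if zero_rows.any():
        for i in np.flatnonzero(zero_rows):
            zero = dk[i] == 0
            preds[i] = targets[i][zero].mean()
    rest = ~zero_rows
    if rest.any():
        if weighting == "uniform":
            w = np.ones_like(dk[rest])
        elif weighting == "inverse":
            w = 1.0 / dk[rest]
        elif weighting == "inverse_squared":
            w = 1.0 / dk[rest] ** 2
        else:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        preds[rest] = (w * targets[rest]).sum(axis=1) / w.sum(axis=1)
    return preds


def knn_predict(
    model: SOMModel,
    observed: Mapping[str, float],
    target_task: str,
    k: int = 3,
    weighting: str = "inverse",
) -> float:
    """Predict one task score from the others via the K nearest nodes.

    Nodes are ranked by Euclidean distance in the observed-task subspace;
    the prediction is the inverse-distance-weighted mean of their target
    elements (the closest node has the highest weight).  If any selected
    node matches the observed sub-vector exactly, the prediction is the
    unweighted mean of the zero-distance nodes' target elements.
    """
    if target_task not in model.task_names:
        raise ValueError(f"unknown target task {target_task!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > model.n_nodes:
        raise ValueError("k cannot exceed the number of nodes")
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}")
    target_idx = model.task_names.index(target_task)
    other = [t for t in model.task_names if t != target_task]
    missing = [t for t in other if t not in observed]
    if missing:
        raise ValueError(f"observed vector missing tasks: {missing}")
    obs_idx = np.array([model.task_names.index(t) for t in other])
    x = np.array([[float(observed[t]) for t in other]])
    return float(
        _subspace_prediction(model.weights, x, obs_idx, target_idx, k, weighting)[0]
    )


def predict_table(
    model: SOMModel, table: ScoreTable, k: int = 3, weighting: str = "inverse"
) -> np.ndarray:
    """Leave-one-task-out predictions for every row and task.

    Returns an array shaped like ``table.scores`` whose column j holds the
    prediction of task j from the remaining tasks.
    """
    if tuple(table.task_names) != tuple(model.task_names):
        raise ValueError("table task set does not match the model")
    n_tasks = table.n_tasks
    preds = np.empty_like(table.scores)
    for j in range(n_tasks):
        obs_idx = np.array([i for i in range(n_tasks) if i != j])
        preds[:, j] = _subspace_prediction(
            model.weights, table.scores[:, obs_idx], obs_idx, j, k, weighting
        )
    return preds


def _shuffled_null(
    predicted: np.ndarray, true_scores: np.ndarray, n_shuffles: int, rng: np.random.Generator
) -> np.ndarray:
    """Null MAEs from shuffling the predicted scores against the true ones."""
    m = len(predicted)
    idx = np.tile(np.arange(m), (n_shuffles, 1))
    idx = rng.permuted(idx, axis=1)
    return np.abs(predicted[idx] - true_scores[None, :]).mean(axis=1)


def permutation_p(
    predicted: Sequence[float],
    true_scores: Sequence[float],
    n_shuffles: int = 1000,
    seed: int = 0,
    direction: str = "better",
) -> PermutationResult:
    """Permutation test of mean absolute prediction error against chance.

    The observed statistic is mean(|predicted - true|); each null value
    re-pairs a shuffled copy of the predictions with the true scores.  With
    ``direction="better"`` (default) small p means the map predicts better
    than chance: p = (1 + #{null <= observed}) / (1 + n_shuffles).  The
    alternative ``direction="literal"`` counts null values greater than the
    observed error instead.
    """
    predicted = np.asarray(predicted, dtype=float)
    true_scores = np.asarray(true_scores, dtype=float)
    if predicted.shape != true_scores.shape or predicted.ndim != 1:
        raise ValueError("predicted and true_scores must be equal-length vectors")
    if len(predicted) < 2:
        raise ValueError("at least 2 observations are required")
    rng = np.random.default_rng(seed)
    observed = float(np.abs(predicted - true_scores).mean())
    null = _shuffled_null(predicted, true_scores, n_shuffles, rng)
    if direction == "better":
        count = int((null <= observed).sum())
    elif direction == "literal":
        count = int((null > observed).sum())
    else:
        raise ValueError("direction must be 'better' or 'literal'")
    return PermutationResult(
        observed_statistic=observed,
        null_values=null,
        n_resamples=n_shuffles,
        p_value=(1 + count) / (1 + n_shuffles),
        seed=seed,
    )


def cross_validate(
    data: ScoreTable,
    som_config: SOMConfig,
    n_reps: int = 1000,
    holdout_fraction: float = 0.2,
    k: int = 3,
    shuffles_per_rep: int = 100,
    seed: int = 0,
    weighting: str = "inverse",
) -> CVReport:
    """Leave-N-out cross-validation with shuffled-prediction nulls.

    Each repetition removes ``floor(holdout_fraction * N)`` participants,
    trains a map on the remainder, predicts every held-out participant's
    score on each task from their other tasks, and builds a within-rep null
    by shuffling the predictions ``shuffles_per_rep`` times.  Nulls pool
    across repetitions; the pooled per-task p compares the mean MAE against
    that pooled null (add-one convention).
    """
    n = data.n_participants
    holdout = int(np.floor(holdout_fraction * n))
    if holdout < 1:
        raise ValueError("holdout_fraction leaves no held-out participants")
    if n - holdout < 3:
        raise ValueError("training split too small to fit a map")
    rng = np.random.default_rng(seed)
    n_tasks = data.n_tasks
    rep_mae = np.empty((n_reps, n_tasks))
    rep_p = np.empty((n_reps, n_tasks))
    pooled_null = np.empty((n_reps, shuffles_per_rep, n_tasks))
    for rep in range(n_reps):
        perm = rng.permutation(n)
        test = data.subset(perm[:holdout])
        train = data.subset(perm[holdout:])
        model = batch_train(train, som_config)
        preds = predict_table(model, test, k=k, weighting=weighting)
        errors = np.abs(preds - test.scores)
        rep_mae[rep] = errors.mean(axis=0)
        for j in range(n_tasks):
            null = _shuffled_null(preds[:, j], test.scores[:, j], shuffles_per_rep, rng)
            pooled_null[rep, :, j] = null
            rep_p[rep, j] = (1 + int((null <= rep_mae[rep, j]).sum())) / (1 + shuffles_per_rep)
    mean_mae = rep_mae.mean(axis=0)
    flat_null = pooled_null.reshape(-1, n_tasks)
    pooled_p = (1 + (flat_null <= mean_mae[None, :]).sum(axis=0)) / (1 + flat_null.shape[0])
    return CVReport(
        task_names=data.task_names,
        per_task_mae=mean_mae,
        per_task_p=pooled_p,
        per_rep_mae=rep_mae,
        per_rep_p=rep_p,
        n_reps=n_reps,
        holdout_fraction=holdout_fraction,
        k_neighbours=k,
        shuffles_per_rep=shuffles_per_rep,
        seed=seed,
    )


def generalization_errors(
    model: SOMModel,
    external: ScoreTable,
    k: int = 3,
    n_shuffles: int = 1000,
    seed: int = 0,
    weighting: str = "inverse",
) -> GeneralizationReport:
    """Prediction errors of a fixed map on an external cohort.

    Leave-one-task-out predictions for every participant, per-task MAE, and
    a shuffled-prediction permutation null per task.
    """
    if tuple(external.task_names) != tuple(model.task_names):
        raise ValueError("external table task set does not match the model")
    preds = predict_table(model, external, k=k, weighting=weighting)
    mae = np.abs(preds - external.scores).mean(axis=0)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=external.n_tasks)
    results = tuple(
        permutation_p(preds[:, j], external.scores[:, j], n_shuffles, int(seeds[j]))
        for j in range(external.n_tasks)
    )
    return GeneralizationReport(
        task_names=model.task_names, per_task_mae=mae, per_task_result=results
    )


def compare_error_sets(
    errors_a: Sequence[float],
    errors_b: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided permutation test for a difference in mean prediction error.

    The observed statistic is |mean(a) - mean(b)|; the null reassigns the
    pooled errors to the two groups at random, preserving group sizes.  The
    pooled sample is canonicalized (sorted, smaller group permuted first) so
    the result is exactly invariant under swapping the two groups.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both error sets must be nonempty")
    observed = float(abs(a.mean() - b.mean()))
    pooled = np.sort(np.concatenate([a, b]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_small = min(a.size, b.size)
    for i in range(n_perm):
        perm = rng.permutation(pooled.size)
        null[i] = abs(pooled[perm[:n_small]].mean() - pooled[perm[n_small:]].mean())
    count = int((null >= observed).sum())
    return PermutationResult(
        observed_statistic=observed,
        null_values=null,
        n_resamples=n_perm,
        p_value=(1 + count) / (1 + n_perm),
        seed=seed,
    )
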