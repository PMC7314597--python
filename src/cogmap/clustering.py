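"""Subgroup discovery: K-means on node weights, BMU-based allocation.

K-means partitions the map's node-weight vectors into k homogeneous
profiles; participants inherit the cluster of their Best Matching Unit.
Cluster labels are reordered so cluster 1 always has the highest centroid
grand mean, making solutions comparable across runs.  Silhouette widths
assess cluster quality over a range of k, and a retrain-stability analysis
measures how reproducible the participant partition is when the map is
retrained on a bootstrap resample of the cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .datasets import ScoreTable
from .som import SOMConfig, SOMModel, batch_train

__all__ = [
    "ClusterSolution",
    "StabilityReport",
    "kmeans_nodes",
    "allocate_to_clusters",
    "silhouette_scan",
    "stability_analysis",
    "profile_summary",
]


@dataclass(frozen=True)
class ClusterSolution:
    """K-means partition of map nodes with a deterministic label order.

    ``node_labels`` are 1-based; cluster 1 has the highest centroid grand
    mean and grand means are non-increasing in the label.
    """

    k: int
    node_labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        doc = {
            "k": self.k,
            "node_labels": [int(v) for v in self.node_labels],
            "centroids": [[float(v) for v in row] for row in self.centroids],
            "inertia": self.inertia,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterSolution":
        doc = json.loads(Path(path).read_text())
        return cls(
            k=int(doc["k"]),
            node_labels=np.array(doc["node_labels"], dtype=int),
            centroids=np.array(doc["centroids"], dtype=float),
            inertia=float(doc["inertia"]),
            seed=int(doc["seed"]),
        )


@dataclass(frozen=True)
class StabilityReport:
    """Agreement of participant partitions across retrained maps."""

    n_reps: int
    pairwise_agreement: np.ndarray  # adjusted Rand index per rep pair
    mean_agreement: float
    min_agreement: float


def kmeans_nodes(
    model: SOMModel, k: int = 4, n_restarts: int = 100, seed: int = 0
) -> ClusterSolution:
    """Best-of-restarts K-means on the node-weight vectors.

    Labels are renumbered so centroid grand means descend with the cluster
    label (cluster 1 = highest-performing profile).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > model.n_nodes:
        raise ValueError("k cannot exceed the number of nodes")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2**32)).fit(model.weights)
    raw_labels = km.labels_
    centroids = km.cluster_centers_
    grand = centroids.mean(axis=1)
    order = np.argsort(-grand, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterSolution(
        k=k,
        node_labels=relabel[raw_labels],
        centroids=centroids[order],
        inertia=float(km.inertia_),
        seed=seed,
    )


def allocate_to_clusters(
    model: SOMModel, solution: ClusterSolution, scores: ScoreTable
) -> pd.DataFrame:
    """Participant -> BMU -> cluster lookup.

    Returns a frame with columns ``participant_id``, ``bmu``, ``cluster``.
    """
    if tuple(scores.task_names) != tuple(model.task_names):
        raise ValueError("table task set does not match the model")
    bmu = model.bmus(scores.scores)
    return pd.DataFrame(
        {
            "participant_id": list(scores.ids),
            "bmu": bmu,
            "cluster": solution.node_labels[bmu],
        }
    )


def silhouette_scan(
    model: SOMModel, k_range, seed: int = 0, n_restarts: int = 20
) -> dict[int, float]:
    """Mean silhouette width of the node partition for each k.

    k < 2 is excluded with a warning (silhouette undefined); the all-
    singleton solution k = n_nodes scores 0 by convention.
    """
    results: dict[int, float] = {}
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(list(k_range)))
    for k, k_seed in zip(k_range, seeds):
        if k < 2:
            warnings.warn(f"silhouette undefined for k={k}; excluded", stacklevel=2)
            continue
        if k > model.n_nodes:
            raise ValueError(f"k={k} exceeds the number of nodes")
        if k == model.n_nodes:
            results[k] = 0.0  # every cluster a singleton
            continue
        sol = kmeans_nodes(model, k=k, n_restarts=n_restarts, seed=int(k_seed))
        results[k] = float(silhouette_score(model.weights, sol.node_labels))
    return results


def _stability_partition(
    data: ScoreTable, som_config: SOMConfig, k: int, rep_seed: int, n_restarts: int
) -> np.ndarray:
    """One stability repetition: bootstrap the cohort, retrain, reallocate.

    The map is retrained on a resample of the participants (drawn with
    replacement) so that retraining genuinely varies between repetitions,
    then the *full* original cohort is allocated through the new map.
    """
    rng = np.random.default_rng(rep_seed)
    idx = rng.integers(0, data.n_participants, size=data.n_participants)
    resample = ScoreTable(
        ids=tuple(f"B{i}" for i in range(data.n_participants)),
        scores=data.scores[idx],
        task_names=data.task_names,
    )
    model = batch_train(resample, som_config)
    solution = kmeans_nodes(model, k=k, n_restarts=n_restarts, seed=rep_seed)
    bmu = model.bmus(data.scores)
    return solution.node_labels[bmu]


def stability_analysis(
    data: ScoreTable,
    som_config: SOMConfig,
    k: int = 4,
    n_reps: int = 1000,
    seed: int = 0,
    n_restarts: int = 20,
    max_pairs: int = 2000,
) -> StabilityReport:
    """Retrain-stability of the participant partition.

    Each repetition retrains the map (on a bootstrap resample of the
    cohort), reclusters the nodes, and allocates every participant; the
    adjusted Rand index between repetition partitions measures robustness.
    """
    if n_reps < 2:
        raise ValueError("stability requires at least 2 repetitions")
    if np.allclose(data.scores, data.scores[0]):
        raise ValueError("degenerate data: all participants identical")
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    partitions = [
        _stability_partition(data, som_config, k, int(s), n_restarts) for s in rep_seeds
    ]
    pairs = list(combinations(range(n_reps), 2))
    if len(pairs) > max_pairs:
        pick = np.random.default_rng(seed + 1).choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in pick]
    ari = np.array([adjusted_rand_score(partitions[i], partitions[j]) for i, j in pairs])
    return StabilityReport(
        n_reps=n_reps,
        pairwise_agreement=ari,
        mean_agreement=float(ari.mean()),
        min_agreement=float(ari.min()),
    )


def profile_summary(allocations: pd.DataFrame, scores: ScoreTable) -> pd.DataFrame:
    """Per-cluster per-task mean, standard error and 95% CI.

    Clusters that received no participants are reported with null
    statistics and a warning.
    """
    if list(allocations["participant_id"]) != list(scores.ids):
        raise ValueError("allocations must cover the score table in order")
    rows = []
    clusters = np.asarray(allocations["cluster"])
    for cluster in range(1, int(clusters.max()) + 1):
        mask = clusters == cluster
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"cluster {cluster} is empty", stacklevel=2)
        for j, task in enumerate(scores.task_names):
            if n == 0:
                rows.append((cluster, task, 0, np.nan, np.nan, np.nan, np.nan))
                continue
            vals = scores.scores[mask, j]
            mean = vals.mean()
            se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            rows.append((cluster, task, n, mean, se, mean - 1.96 * se, mean + 1.96 * se))
    return pd.DataFrame(
        rows, columns=["cluster", "task", "n", "mean", "se", "ci_lower", "ci_upper"]
    )
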