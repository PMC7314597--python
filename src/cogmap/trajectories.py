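"""Pre/post trajectory mapping and interest-group analysis.

Participants from a training study are allocated into the baseline map's
clusters separately at pre- and post-training; the transition between
cluster labels defines their improvement trajectory.  Four "interest
groups" are analysed: movers into clusters 1-3 (only participants who
arrived from outside) and stayers in cluster 4 (the lowest-performing
profile).  Gain scores (post minus pre) and an external covariate (for
example a fluid-intelligence score) are compared across interest groups
with one-way ANOVAs and Tukey HSD post-hoc tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterSolution, allocate_to_clusters
from .datasets import ScoreTable
from .som import SOMModel
from .stats import AnovaResult, TukeyResult, oneway_anova, tukey_hsd

__all__ = [
    "INTEREST_GROUPS",
    "allocate_timepoints",
    "interest_groups",
    "trajectory_report",
    "treatment_time_interaction",
    "TrajectoryReport",
]

INTEREST_GROUPS = ("mover_to_1", "mover_to_2", "mover_to_3", "stayer_in_4", "other")


def allocate_timepoints(
    model: SOMModel,
    solution: ClusterSolution,
    pre: ScoreTable,
    post: ScoreTable,
) -> pd.DataFrame:
    """Cluster labels at both timepoints plus per-task gain scores.

    The returned transition table has one row per participant with columns
    ``cluster_pre``, ``cluster_post``, ``bmu_pre``, ``bmu_post``,
    ``gain_<task>`` for every task, and any covariates attached to the pre
    table.
    """
    if pre.ids != post.ids:
        only_pre = sorted(set(pre.ids) - set(post.ids))
        only_post = sorted(set(post.ids) - set(pre.ids))
        raise ValueError(
            "pre and post tables must contain identical participants in identical "
            f"order (only in pre: {only_pre[:5]}, only in post: {only_post[:5]})"
        )
    alloc_pre = allocate_to_clusters(model, solution, pre)
    alloc_post = allocate_to_clusters(model, solution, post)
    table = pd.DataFrame(
        {
            "participant_id": list(pre.ids),
            "cluster_pre": alloc_pre["cluster"].to_numpy(),
            "cluster_post": alloc_post["cluster"].to_numpy(),
            "bmu_pre": alloc_pre["bmu"].to_numpy(),
            "bmu_post": alloc_post["bmu"].to_numpy(),
        }
    )
    gains = post.scores - pre.scores
    for j, task in enumerate(pre.task_names):
        table[f"gain_{task}"] = gains[:, j]
    for name, col in pre.covariates.items():
        table[name] = col
    table.attrs["task_names"] = tuple(pre.task_names)
    return table


def interest_groups(transitions: pd.DataFrame) -> pd.Series:
    """Classify each transition into one of the five interest categories.

    Movers to cluster c (c in 1..3) arrived at c from a different cluster;
    stayers in 4 were in cluster 4 at both timepoints.  Everything else —
    including participants already in clusters 1-3 who remained there, and
    participants who fell into cluster 4 — is ``other``.
    """
    pre = transitions["cluster_pre"].to_numpy()
    post = transitions["cluster_post"].to_numpy()
    if np.any((pre < 1) | (pre > 4) | (post < 1) | (post > 4)):
        raise ValueError("interest groups are defined for cluster labels 1..4")
    labels = np.full(len(pre), "other", dtype=object)
    for c in (1, 2, 3):
        labels[(post == c) & (pre != c)] = f"mover_to_{c}"
    labels[(pre == 4) & (post == 4)] = "stayer_in_4"
    return pd.Series(
        pd.Categorical(labels, categories=list(INTEREST_GROUPS)),
        index=transitions.index,
        name="interest_group",
    )


@dataclass(frozen=True)
class TrajectoryReport:
    """Group statistics for the interest-group analysis."""

    groups: tuple[str, ...]
    group_sizes: dict[str, int]
    gain_anova: dict[str, AnovaResult]
    gain_tukey: dict[str, TukeyResult]
    gain_means: pd.DataFrame  # group x task means of gains
    covariate_name: str | None
    covariate_anova: AnovaResult | None
    covariate_tukey: TukeyResult | None
    covariate_means: dict[str, tuple[float, float]] | None  # group -> (mean, sd)
    transition_counts: np.ndarray  # 4 x 4, pre x post

    def to_json(self, path: str | Path) -> None:
        def anova_doc(a: AnovaResult) -> dict:
            return {"F": a.F, "df_between": a.df_between, "df_within": a.df_within, "p": a.p}

        def tukey_doc(t: TukeyResult) -> dict:
            return {
                "group_means": [float(v) for v in t.group_means],
                "pvalues": [[float(v) for v in row] for row in t.pvalues],
                "reject": [[bool(v) for v in row] for row in t.reject],
                "alpha": t.alpha,
            }

        doc = {
            "groups": list(self.groups),
            "group_sizes": self.group_sizes,
            "gain_anova": {t: anova_doc(a) for t, a in self.gain_anova.items()},
            "gain_tukey": {t: tukey_doc(v) for t, v in self.gain_tukey.items()},
            "gain_means": self.gain_means.to_dict(),
            "covariate_name": self.covariate_name,
            "covariate_anova": anova_doc(self.covariate_anova) if self.covariate_anova else None,
            "covariate_tukey": tukey_doc(self.covariate_tukey) if self.covariate_tukey else None,
            "covariate_means": self.covariate_means,
            "transition_counts": [[int(v) for v in row] for row in self.transition_counts],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def transition_matrix(transitions: pd.DataFrame, n_clusters: int = 4) -> np.ndarray:
    """Pre x post cluster transition counts."""
    counts = np.zeros((n_clusters, n_clusters), dtype=int)
    for pre, post in zip(transitions["cluster_pre"], transitions["cluster_post"]):
        counts[int(pre) - 1, int(post) - 1] += 1
    return counts


def trajectory_report(
    transitions: pd.DataFrame,
    grouping: pd.Series,
    covariate_name: str | None = None,
    alpha: float = 0.05,
) -> TrajectoryReport:
    """ANOVA + Tukey comparison of gains (and a covariate) across groups.

    Interest groups with fewer than 2 members are excluded with a warning;
    the ``other`` category is never analysed.  At least two analysable
    groups are required.
    """
    task_names = transitions.attrs.get(
        "task_names",
        tuple(c[len("gain_") :] for c in transitions.columns if c.startswith("gain_")),
    )
    if covariate_name is not None and covariate_name not in transitions.columns:
        raise ValueError(f"covariate {covariate_name!r} not present in the transition table")
    candidate = [g for g in INTEREST_GROUPS if g != "other"]
    groups = []
    for g in candidate:
        n = int((grouping == g).sum())
        if n >= 2:
            groups.append(g)
        elif n > 0:
            warnings.warn(f"interest group {g} has n={n} < 2; excluded", stacklevel=2)
    if len(groups) < 2:
        raise ValueError("at least two non-empty interest groups are required")
    masks = {g: (grouping == g).to_numpy() for g in groups}
    gain_anova, gain_tukey = {}, {}
    mean_rows = {}
    for task in task_names:
        col = transitions[f"gain_{task}"].to_numpy()
        samples = [col[masks[g]] for g in groups]
        gain_anova[task] = oneway_anova(samples)
        gain_tukey[task] = tukey_hsd(samples, alpha=alpha)
        mean_rows[task] = [s.mean() for s in samples]
    gain_means = pd.DataFrame(mean_rows, index=groups)
    cov_anova = cov_tukey = cov_means = None
    if covariate_name is not None:
        col = transitions[covariate_name].to_numpy(dtype=float)
        samples = [col[masks[g]] for g in groups]
        cov_anova = oneway_anova(samples)
        cov_tukey = tukey_hsd(samples, alpha=alpha)
        cov_means = {
            g: (float(s.mean()), float(s.std(ddof=1))) for g, s in zip(groups, samples)
        }
    return TrajectoryReport(
        groups=tuple(groups),
        group_sizes={g: int(masks[g].sum()) for g in groups},
        gain_anova=gain_anova,
        gain_tukey=gain_tukey,
        gain_means=gain_means,
        covariate_name=covariate_name,
        covariate_anova=cov_anova,
        covariate_tukey=cov_tukey,
        covariate_means=cov_means,
        transition_counts=transition_matrix(transitions),
    )


def treatment_time_interaction(
    group_labels,
    pre_scores: ScoreTable,
    post_scores: ScoreTable,
) -> dict[str, AnovaResult]:
    """Treatment x time interaction of a two-way mixed ANOVA, per task.

    Between-subject factor: treatment group; within-subject factor: time
    (pre/post, paired per participant).  With a two-level within factor the
    interaction F with classical sums of squares is exactly the one-way
    ANOVA F on the gain scores (post minus pre) across groups, with
    df = (g - 1, N - g); it is computed that way here.
    """
    if pre_scores.ids != post_scores.ids:
        raise ValueError("pre and post tables must pair identical participants in order")
    labels = np.asarray(group_labels)
    if labels.shape != (pre_scores.n_participants,):
        raise ValueError("one group label per participant is required")
    unique = pd.unique(labels)
    if len(unique) < 2:
        raise ValueError("at least two treatment groups are required")
    gains = post_scores.scores - pre_scores.scores
    out = {}
    for j, task in enumerate(pre_scores.task_names):
        samples = [gains[labels == g, j] for g in unique]
        out[task] = oneway_anova(samples)
    return out
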