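"""Score tables and synthetic cohort generation.

The pipeline operates on tables of age-standardized cognitive assessment
scores (nominal scale mean 100, SD 15): one row per participant, one column
per assessment task.  Because the original study cohorts are not publicly
deposited, this module also provides a synthetic-cohort generator that
emulates their published marginal statistics — a four-profile mixture of
multivariate-normal performance profiles, training gains that differ by
profile, and a fluid-intelligence covariate correlated with improvement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_TASKS",
    "BASELINE_TASK_MEANS",
    "BASELINE_TASK_SDS",
    "TRAINING_PRE_MEANS",
    "TRAINING_PRE_SDS",
    "TRAINING_POST_MEANS",
    "TRAINING_POST_SDS",
    "ScoreTable",
    "Profile",
    "CohortSpec",
    "PairedScoreTables",
    "SchemaError",
    "ValidationError",
    "simulate_baseline_cohort",
    "simulate_training_cohort",
    "read_score_table",
    "write_score_table",
    "default_baseline_spec",
    "default_training_spec",
    "separated_baseline_spec",
    "separated_training_spec",
]

#: Default task battery: two verbal span tasks (forward/backward digit recall)
#: and two visuospatial span tasks (dot matrix, Mr. X).
DEFAULT_TASKS: tuple[str, ...] = ("forward_digit", "dot_matrix", "backward_digit", "mr_x")

# Published marginal summary statistics used as calibration targets for the
# synthetic cohorts (combined referred + community baseline sample, N=616, and
# the adaptive training sample, N=179, pre and post training).
BASELINE_TASK_MEANS = (93.86, 93.46, 92.81, 98.64)
BASELINE_TASK_SDS = (15.84, 15.41, 14.00, 15.26)
TRAINING_PRE_MEANS = (93.95, 90.78, 85.58, 89.73)
TRAINING_PRE_SDS = (15.58, 16.12, 14.90, 16.16)
TRAINING_POST_MEANS = (100.54, 110.56, 101.01, 102.53)
TRAINING_POST_SDS = (17.64, 19.59, 15.43, 18.68)

N_BASELINE = 616
N_TRAINING = 179


class SchemaError(ValueError):
    """A required column is absent or malformed in a delimited score file."""


class ValidationError(ValueError):
    """Table contents violate a ScoreTable invariant."""


@dataclass(frozen=True)
class ScoreTable:
    """Participants x tasks matrix of standardized scores.

    Parameters
    ----------
    ids
        Unique participant identifiers, one per row.
    scores
        Real-valued matrix, shape ``(n_participants, n_tasks)``; no missing
        values are permitted.
    task_names
        Ordered task labels matching the score columns.
    timepoint
        Optional label for the whole table (``"pre"``, ``"post"``,
        ``"baseline"``).
    covariates
        Optional named real-valued columns aligned with ``ids`` (for example
        ``gf_score`` or ``age_years``).
    """

    ids: tuple[str, ...]
    scores: np.ndarray
    task_names: tuple[str, ...] = DEFAULT_TASKS
    timepoint: str | None = None
    covariates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "task_names", tuple(self.task_names))
        if scores.ndim != 2:
            raise ValidationError("scores must be a 2-D matrix")
        if len(self.ids) != scores.shape[0]:
            raise ValidationError("number of ids must match number of score rows")
        if len(self.task_names) != scores.shape[1]:
            raise ValidationError("task_names length must match number of score columns")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise ValidationError(f"duplicate participant_id values: {dupes}")
        if not np.all(np.isfinite(scores)):
            raise ValidationError("scores contain missing or non-finite values")
        covs = {k: np.asarray(v, dtype=float) for k, v in self.covariates.items()}
        for name, col in covs.items():
            if col.shape != (scores.shape[0],):
                raise ValidationError(f"covariate {name!r} length must match participants")
        object.__setattr__(self, "covariates", covs)

    @property
    def n_participants(self) -> int:
        return self.scores.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=list(self.task_names))
        df.insert(0, "participant_id", list(self.ids))
        if self.timepoint is not None:
            df["timepoint"] = self.timepoint
        for name, col in self.covariates.items():
            df[name] = col
        return df

    def subset(self, index: np.ndarray) -> "ScoreTable":
        """Row subset (or reordering) by integer index array."""
        index = np.asarray(index)
        return ScoreTable(
            ids=tuple(np.asarray(self.ids, dtype=object)[index]),
            scores=self.scores[index],
            task_names=self.task_names,
            timepoint=self.timepoint,
            covariates={k: v[index] for k, v in self.covariates.items()},
        )


@dataclass(frozen=True)
class Profile:
    """One mixture component: centroid, within-profile covariance, weight."""

    centroid: np.ndarray
    covariance: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``profiles`` define a Gaussian-mixture of performance profiles.  The
    optional gain parameters describe post-training change per profile, and
    the optional ``gf_mean_by_profile`` attaches a fluid-intelligence
    covariate whose mean varies with the hidden profile.
    """

    n_participants: int
    profiles: tuple[Profile, ...]
    gain_means: tuple[np.ndarray, ...] | None = None
    gain_sd: float = 0.0
    gf_mean_by_profile: tuple[float, ...] | None = None
    gf_sd: float = 10.0
    seed: int = 0
    task_names: tuple[str, ...] = DEFAULT_TASKS

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValidationError("n_participants must be positive")
        profiles = tuple(self.profiles)
        object.__setattr__(self, "profiles", profiles)
        n_tasks = len(self.task_names)
        weights = np.array([p.weight for p in profiles])
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ValidationError("mixing weights must be nonnegative and sum to 1")
        for p in profiles:
            if p.centroid.shape != (n_tasks,):
                raise ValidationError("centroid length must equal task count")
            cov = p.covariance
            if cov.shape != (n_tasks, n_tasks) or not np.allclose(cov, cov.T):
                raise ValidationError("covariance must be a symmetric task x task matrix")
            eigs = np.linalg.eigvalsh(cov)
            if eigs.min() < -1e-8 * max(eigs.max(), 1.0):
                raise ValidationError("covariance matrix is not positive semidefinite")
        if self.gain_means is not None:
            gains = tuple(np.asarray(g, dtype=float) for g in self.gain_means)
            if len(gains) != len(profiles):
                raise ValidationError("one gain vector per profile is required")
            for g in gains:
                if g.shape != (n_tasks,):
                    raise ValidationError("gain vector length must equal task count")
            object.__setattr__(self, "gain_means", gains)
        if self.gain_sd < 0:
            raise ValidationError("gain_sd must be nonnegative")
        if self.gf_mean_by_profile is not None:
            if len(self.gf_mean_by_profile) != len(profiles):
                raise ValidationError("one gf mean per profile is required")
            if self.gf_sd <= 0:
                raise ValidationError("gf_sd must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.profiles])


@dataclass(frozen=True)
class PairedScoreTables:
    """Pre/post tables for one training cohort plus hidden profile labels."""

    pre: ScoreTable
    post: ScoreTable
    true_profile: np.ndarray

    def __post_init__(self) -> None:
        if self.pre.ids != self.post.ids:
            raise ValidationError("pre and post tables must share identical participant order")
        object.__setattr__(self, "true_profile", np.asarray(self.true_profile, dtype=int))
        if self.true_profile.shape != (self.pre.n_participants,):
            raise ValidationError("one hidden profile label per participant is required")


# ---------------------------------------------------------------------------
# Default cohort specifications
# ---------------------------------------------------------------------------

# Profile offsets (added to the target marginal mean vector).  Four profiles:
# high-all, mid-flat, mid with visuospatial > verbal, low-all.  Equal mixing
# weights, offsets sum to zero per task so the mixture mean hits the target
# exactly.  Task order: (forward_digit, dot_matrix, backward_digit, mr_x) —
# verbal tasks at indices 0, 2; visuospatial at 1, 3.
_PROFILE_OFFSETS = np.array(
    [
        [19.0, 11.0, 19.0, 11.0],   # high performers across the board
        [0.0, 0.0, 0.0, 0.0],       # average, flat profile
        [-8.0, 8.0, -8.0, 8.0],     # visuospatial above verbal
        [-11.0, -19.0, -11.0, -19.0],  # low performers across the board
    ]
)
_WITHIN_CORR = 0.3  # default inter-task correlation within a profile

# Per-profile additive gain offsets (same for every task) and i.i.d. gain
# noise SD; chosen together with the offsets above so the realized pooled-SD
# effect sizes in a simulated adaptive cohort land near the published values.
# The visuospatial-strength profile benefits most, matching the visuospatial
# emphasis of the training content.
_GAIN_OFFSETS = np.array([-2.0, -2.0, 6.0, -2.0])
_GAIN_SD = 7.9
_GF_MEANS = (96.0, 96.0, 111.0, 96.0)
_GF_SD = 10.0


def _mixture_profiles(
    means: Sequence[float], sds: Sequence[float], offsets: np.ndarray, within_corr: float
) -> tuple[Profile, ...]:
    """Equal-weight profiles whose mixture matches target marginal moments.

    Within-profile variance per task is the target variance minus the
    between-profile variance contributed by the offsets (equal weights, zero
    offset mean), so that the mixture's marginal SD matches the target.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    k, n_tasks = offsets.shape
    between_var = (offsets**2).mean(axis=0)
    within_var = sds**2 - between_var
    if np.any(within_var <= 0):
        raise ValidationError("profile offsets exceed the target marginal variance")
    within_sd = np.sqrt(within_var)
    corr = np.full((n_tasks, n_tasks), within_corr)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(within_sd, within_sd)
    return tuple(
        Profile(centroid=means + offsets[i], covariance=cov, weight=1.0 / k) for i in range(k)
    )


def default_baseline_spec(n_participants: int = N_BASELINE, seed: int = 0) -> CohortSpec:
    """Baseline cohort calibrated to the published combined-sample marginals."""
    return CohortSpec(
        n_participants=n_participants,
        profiles=_mixture_profiles(
            BASELINE_TASK_MEANS, BASELINE_TASK_SDS, _PROFILE_OFFSETS, _WITHIN_CORR
        ),
        seed=seed,
    )


def default_training_spec(n_participants: int = N_TRAINING, seed: int = 0) -> CohortSpec:
    """Training cohort calibrated to the published adaptive-group marginals.

    Mean gains are the published post-minus-pre means; per-profile additive
    offsets make improvement depend on the hidden profile, and the gf
    covariate mean follows the same ordering, so fluid intelligence predicts
    improvement.
    """
    pre = np.asarray(TRAINING_PRE_MEANS)
    post = np.asarray(TRAINING_POST_MEANS)
    base_gain = post - pre
    return CohortSpec(
        n_participants=n_participants,
        profiles=_mixture_profiles(
            TRAINING_PRE_MEANS, TRAINING_PRE_SDS, _PROFILE_OFFSETS, _WITHIN_CORR
        ),
        gain_means=tuple(base_gain + off for off in _GAIN_OFFSETS),
        gain_sd=_GAIN_SD,
        gf_mean_by_profile=_GF_MEANS,
        gf_sd=_GF_SD,
        seed=seed,
    )


# Roughly equidistant centroids (simplex-like) with distinct grand means:
# high-all, verbal-strength, visuospatial-strength, low-all.  Near-equal
# pairwise separation keeps the map free of long interpolation bands that
# would otherwise soak up a K-means cluster.
_SEPARATED_OFFSETS = np.array(
    [
        [16.0, 16.0, 16.0, 16.0],
        [17.0, -13.0, 17.0, -13.0],
        [-15.0, 15.0, -15.0, 15.0],
        [-16.0, -16.0, -16.0, -16.0],
    ]
)


def separated_baseline_spec(
    n_participants: int = N_BASELINE, seed: int = 0, within_sd: float = 5.0
) -> CohortSpec:
    """Four well-separated profiles (tight within-profile spread).

    Used for structure-recovery experiments where the ground-truth partition
    must be recoverable; marginals are no longer calibrated to the published
    table.
    """
    means = np.asarray(BASELINE_TASK_MEANS)
    corr = np.full((4, 4), 0.2)
    np.fill_diagonal(corr, 1.0)
    cov = corr * within_sd**2
    profiles = tuple(
        Profile(centroid=means + off, covariance=cov, weight=0.25) for off in _SEPARATED_OFFSETS
    )
    return CohortSpec(n_participants=n_participants, profiles=profiles, seed=seed)


def separated_training_spec(
    n_participants: int = N_TRAINING, seed: int = 0, within_sd: float = 5.0
) -> CohortSpec:
    """Well-separated profiles with strongly profile-dependent gains.

    Gains are largest for profiles that move participants up the performance
    ladder; the gf covariate mean follows the gain ordering.
    """
    base = separated_baseline_spec(n_participants, seed, within_sd)
    gain = np.asarray(TRAINING_POST_MEANS) - np.asarray(TRAINING_PRE_MEANS)
    gain_offsets = np.array([10.0, 4.0, -4.0, -10.0])
    return dataclasses.replace(
        base,
        gain_means=tuple(gain + off for off in gain_offsets),
        gain_sd=3.0,
        gf_mean_by_profile=(112.0, 102.0, 95.0, 85.0),
        gf_sd=8.0,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_labels_and_scores(spec: CohortSpec, rng: np.random.Generator):
    labels = rng.choice(len(spec.profiles), size=spec.n_participants, p=spec.weights)
    scores = np.empty((spec.n_participants, len(spec.task_names)))
    for i, profile in enumerate(spec.profiles):
        mask = labels == i
        n_i = int(mask.sum())
        if n_i:
            scores[mask] = rng.multivariate_normal(
                profile.centroid, profile.covariance, size=n_i, method="eigh"
            )
    return labels, scores


def _make_ids(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"P{i + 1:0{width}d}" for i in range(n))


def simulate_baseline_cohort(
    spec: CohortSpec, *, return_labels: bool = False, timepoint: str = "baseline"
):
    """Draw one cohort from the profile mixture.

    Each participant's profile index is drawn from the mixing weights, then
    the score vector from that profile's multivariate normal.  Deterministic
    given ``spec.seed``.  With ``return_labels=True`` also returns the hidden
    profile labels (for recovery experiments).
    """
    rng = np.random.default_rng(spec.seed)
    labels, scores = _draw_labels_and_scores(spec, rng)
    covariates = {}
    if spec.gf_mean_by_profile is not None:
        gf_means = np.asarray(spec.gf_mean_by_profile)[labels]
        covariates["gf_score"] = gf_means + rng.normal(0.0, spec.gf_sd, size=len(labels))
    table = ScoreTable(
        ids=_make_ids(spec.n_participants),
        scores=scores,
        task_names=spec.task_names,
        timepoint=timepoint,
        covariates=covariates,
    )
    return (table, labels) if return_labels else table


def simulate_training_cohort(spec: CohortSpec) -> PairedScoreTables:
    """Draw a paired pre/post cohort with profile-dependent gains.

    The pre table is drawn as in :func:`simulate_baseline_cohort`; the post
    table adds each participant's profile gain vector plus i.i.d. Gaussian
    gain noise.  If ``gf_mean_by_profile`` is set, a fluid-intelligence
    covariate is drawn per profile and attached to both tables.
    """
    if spec.gain_means is None:
        raise ValidationError("training cohort requires gain_means in the spec")
    rng = np.random.default_rng(spec.seed)
    labels, pre_scores = _draw_labels_and_scores(spec, rng)
    gain = np.stack(spec.gain_means)[labels]
    if spec.gain_sd > 0:
        gain = gain + rng.normal(0.0, spec.gain_sd, size=pre_scores.shape)
    post_scores = pre_scores + gain
    covariates = {}
    if spec.gf_mean_by_profile is not None:
        gf_means = np.asarray(spec.gf_mean_by_profile)[labels]
        covariates["gf_score"] = gf_means + rng.normal(0.0, spec.gf_sd, size=len(labels))
    ids = _make_ids(spec.n_participants)
    pre = ScoreTable(ids, pre_scores, spec.task_names, "pre", dict(covariates))
    post = ScoreTable(ids, post_scores, spec.task_names, "post", dict(covariates))
    return PairedScoreTables(pre=pre, post=post, true_profile=labels)


# ---------------------------------------------------------------------------
# Delimited text I/O
# ---------------------------------------------------------------------------


def read_score_table(
    path: str | Path,
    task_names: Sequence[str] = DEFAULT_TASKS,
    covariate_names: Sequence[str] = (),
) -> ScoreTable:
    """Read a CSV score table (header row required).

    Required columns: ``participant_id`` plus one numeric column per task.
    Optional: ``timepoint`` (must be constant within a file) and any named
    covariate columns.  Rows with missing or non-numeric task scores are
    rejected with the offending row number.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = ["participant_id", *task_names]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    scores = np.empty((len(df), len(task_names)))
    for j, task in enumerate(task_names):
        numeric = pd.to_numeric(df[task], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise SchemaError(f"non-numeric or missing {task!r} value at file row {row}")
        scores[:, j] = numeric.to_numpy()
    timepoint = None
    if "timepoint" in df.columns:
        values = df["timepoint"].dropna().unique()
        if len(values) > 1:
            raise SchemaError("timepoint column must be constant within one file")
        if len(values) == 1:
            timepoint = str(values[0])
    covariates = {}
    for name in covariate_names:
        if name not in df.columns:
            raise SchemaError(f"missing covariate column {name!r} in {path}")
        covariates[name] = pd.to_numeric(df[name]).to_numpy()
    for name in df.columns:
        if name not in required and name != "timepoint" and name not in covariates:
            numeric = pd.to_numeric(df[name], errors="coerce")
            if not numeric.isna().any():
                covariates[name] = numeric.to_numpy()
    return ScoreTable(
        ids=tuple(df["participant_id"].astype(str)),
        scores=scores,
        task_names=tuple(task_names),
        timepoint=timepoint,
        covariates=covariates,
    )


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a ScoreTable as CSV; ``read_score_table`` round-trips exactly."""
    table.to_frame().to_csv(path, index=False)
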