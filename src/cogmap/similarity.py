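"""Component-plane similarity and bootstrap change tests.

Each task's component plane (one weight element per node) is the map's
representation of that task; the Pearson correlation between two planes
measures how similarly the map represents the two tasks.  To test whether
training changed a pairwise relationship, the node-weight elements of each
map are bootstrap-resampled (jointly for the two tasks within a map, so
their pairing is preserved), the pair correlation is recomputed in both
maps, and the post-minus-pre differences form a resampling distribution;
the change is declared significant when zero falls outside the configured
central interval.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .som import SOMModel
from .stats import nearest_rank_percentile

__all__ = [
    "SimilarityMatrix",
    "DifferenceTest",
    "similarity_matrix",
    "bootstrap_pair_difference",
    "compare_all_pairs",
]

TAIL_RULES = ("two_sided", "paper")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric task x task matrix of component-plane Pearson r."""

    task_names: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.task_names), columns=list(self.task_names))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="task")


@dataclass(frozen=True)
class DifferenceTest:
    """Bootstrap test of a training-induced change in one pair correlation."""

    pair: tuple[str, str]
    r_pre: float
    r_post: float
    boot_differences: np.ndarray
    alpha: float
    tail_rule: str
    lower: float
    upper: float
    reject: bool
    direction: int  # sign of the median bootstrap difference
    seed: int

    def summary(self) -> dict:
        return {
            "pair": list(self.pair),
            "r_pre": self.r_pre,
            "r_post": self.r_post,
            "alpha": self.alpha,
            "tail_rule": self.tail_rule,
            "lower": self.lower,
            "upper": self.upper,
            "reject": bool(self.reject),
            "direction": int(self.direction),
            "seed": self.seed,
        }


def similarity_matrix(model: SOMModel) -> SimilarityMatrix:
    """Pairwise Pearson correlations between component planes."""
    planes = model.weights
    stds = planes.std(axis=0)
    for name, s in zip(model.task_names, stds):
        if s == 0:
            raise ValueError(f"component plane for {name!r} is constant; correlation undefined")
    r = np.corrcoef(planes, rowvar=False)
    r = (r + r.T) / 2.0  # enforce exact symmetry
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(task_names=model.task_names, values=r)


def _rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of x against the matching row of y."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    return num / den


def _model_stream(seed: int, weights: np.ndarray) -> np.random.Generator:
    """Resampling stream keyed to the model's contents, not its role.

    Each map gets its own independent index stream, derived from the seed
    and a digest of its weight matrix.  Because the stream follows the
    model, swapping the pre/post arguments negates every bootstrap
    difference exactly, and comparing a model against itself yields a
    difference distribution that is identically zero.
    """
    key = int.from_bytes(hashlib.sha256(weights.tobytes()).digest()[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def _bootstrap_pair_r(
    planes: np.ndarray, b: int, rng: np.random.Generator, max_retries: int = 100
) -> np.ndarray:
    """Bootstrap correlations of a (n_nodes, 2) plane pair over node resamples."""
    n = planes.shape[0]
    idx = rng.integers(0, n, size=(b, n))
    x, y = planes[idx, 0], planes[idx, 1]
    r = _rowwise_pearson(x, y)
    # resamples that drew a constant plane are redrawn (bounded retries)
    for _ in range(max_retries):
        bad = ~np.isfinite(r)
        if not bad.any():
            break
        idx = rng.integers(0, n, size=(int(bad.sum()), n))
        r[bad] = _rowwise_pearson(planes[idx, 0], planes[idx, 1])
    else:
        raise RuntimeError("could not draw non-constant bootstrap resamples")
    return np.clip(r, -1.0, 1.0)


def bootstrap_pair_difference(
    model_pre: SOMModel,
    model_post: SOMModel,
    task_a: str,
    task_b: str,
    b: int = 10000,
    alpha: float = 0.05,
    tail_rule: str = "two_sided",
    seed: int = 0,
) -> DifferenceTest:
    """Bootstrap the post-minus-pre change in one pair's plane correlation.

    Node indices are drawn with replacement independently within each model
    (node identities do not correspond across separately trained maps), the
    pair correlation recomputed on each resample, and the difference
    r_post - r_pre collected B times.  With ``tail_rule="two_sided"``
    (default) the null of no change is rejected when zero falls outside the
    central 1 - alpha interval (nearest-rank percentiles); ``"paper"``
    rejects when zero falls in the bottom or top alpha tail (a 2*alpha
    rule).
    """
    if tuple(model_pre.task_names) != tuple(model_post.task_names):
        raise ValueError("models must share one task set")
    if tail_rule not in TAIL_RULES:
        raise ValueError(f"tail_rule must be one of {TAIL_RULES}")
    names = model_pre.task_names
    if task_a not in names or task_b not in names:
        raise ValueError(f"unknown task pair ({task_a!r}, {task_b!r})")
    if task_a == task_b:
        raise ValueError("a pair requires two distinct tasks")
    ia, ib = names.index(task_a), names.index(task_b)
    pre = model_pre.weights[:, [ia, ib]]
    post = model_post.weights[:, [ia, ib]]
    for planes, label in ((pre, "pre"), (post, "post")):
        if planes[:, 0].std() == 0 or planes[:, 1].std() == 0:
            raise ValueError(f"constant component plane in the {label} model")
    r_pre = float(np.corrcoef(pre[:, 0], pre[:, 1])[0, 1])
    r_post = float(np.corrcoef(post[:, 0], post[:, 1])[0, 1])
    boot_pre = _bootstrap_pair_r(pre, b, _model_stream(seed, model_pre.weights))
    boot_post = _bootstrap_pair_r(post, b, _model_stream(seed, model_post.weights))
    diffs = boot_post - boot_pre
    if tail_rule == "two_sided":
        lo_q, hi_q = 100 * (alpha / 2), 100 * (1 - alpha / 2)
    else:  # the literal bottom-or-top alpha rule
        lo_q, hi_q = 100 * alpha, 100 * (1 - alpha)
    lower = nearest_rank_percentile(diffs, lo_q)
    upper = nearest_rank_percentile(diffs, hi_q)
    reject = not (lower <= 0.0 <= upper)
    return DifferenceTest(
        pair=(task_a, task_b),
        r_pre=r_pre,
        r_post=r_post,
        boot_differences=diffs,
        alpha=alpha,
        tail_rule=tail_rule,
        lower=lower,
        upper=upper,
        reject=reject,
        direction=int(np.sign(np.median(diffs))),
        seed=seed,
    )


def compare_all_pairs(
    model_pre: SOMModel,
    model_post: SOMModel,
    b: int = 10000,
    alpha: float = 0.05,
    tail_rule: str = "two_sided",
    seed: int = 0,
) -> list[DifferenceTest]:
    """One bootstrap difference test per unordered task pair.

    Per-pair seeds are derived deterministically from ``seed``.
    """
    pairs = list(itertools.combinations(model_pre.task_names, 2))
    pair_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(pairs))
    return [
        bootstrap_pair_difference(
            model_pre, model_post, a, bname, b=b, alpha=alpha, tail_rule=tail_rule, seed=int(s)
        )
        for (a, bname), s in zip(pairs, pair_seeds)
    ]


def write_difference_tests(tests: list[DifferenceTest], path: str | Path) -> None:
    Path(path).write_text(json.dumps([t.summary() for t in tests], indent=1, sort_keys=True))
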