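"""Shared statistical primitives.

Pearson correlation, pooled-SD effect sizes, classical one-way ANOVA and
Tukey HSD post-hoc comparisons, plus a nearest-rank percentile helper used
by the resampling routines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = [
    "EffectSize",
    "AnovaResult",
    "TukeyResult",
    "pearson_r",
    "cohens_d_from_summary",
    "oneway_anova",
    "tukey_hsd",
    "nearest_rank_percentile",
]


@dataclass(frozen=True)
class EffectSize:
    """Standardized pre/post mean difference with its ingredients."""

    d: float
    m_pre: float
    sd_pre: float
    m_post: float
    sd_post: float
    n: int | None = None


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise studentized-range comparisons of group means."""

    group_means: np.ndarray
    pvalues: np.ndarray  # symmetric matrix, diagonal 1
    reject: np.ndarray
    alpha: float


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("correlation requires at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = scipy.stats.pearsonr(x, y).statistic
    return float(np.clip(r, -1.0, 1.0))


def cohens_d_from_summary(
    m_pre: float, sd_pre: float, m_post: float, sd_post: float, n: int | None = None
) -> EffectSize:
    """Pooled-SD standardized mean difference.

    d = (m_post - m_pre) / sqrt((sd_pre**2 + sd_post**2) / 2); the sign of
    the change is preserved.
    """
    if sd_pre <= 0 or sd_post <= 0:
        raise ValueError("standard deviations must be positive")
    pooled = np.sqrt((sd_pre**2 + sd_post**2) / 2.0)
    return EffectSize(
        d=float((m_post - m_pre) / pooled),
        m_pre=m_pre,
        sd_pre=sd_pre,
        m_post=m_post,
        sd_post=sd_post,
        n=n,
    )


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("at least two groups are required")
    for g in arrays:
        if g.ndim != 1 or len(g) < 2:
            raise ValueError("every group must contain at least 2 observations")
    return arrays


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical between/within sum-of-squares decomposition.

    Implemented explicitly so that the fully degenerate case (zero
    between-group variation) yields F = 0, p = 1 rather than NaN.
    """
    arrays = _check_groups(groups)
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = len(arrays) - 1
    df_within = len(all_values) - len(arrays)
    if ss_between == 0:
        return AnovaResult(F=0.0, df_between=df_between, df_within=df_within, p=1.0)
    if ss_within == 0:
        return AnovaResult(F=float("inf"), df_between=df_between, df_within=df_within, p=0.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(scipy.stats.f.sf(f, df_between, df_within))
    return AnovaResult(F=float(f), df_between=df_between, df_within=df_within, p=p)


def tukey_hsd(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> TukeyResult:
    """Tukey's honestly-significant-difference pairwise comparisons."""
    arrays = _check_groups(groups)
    res = scipy.stats.tukey_hsd(*arrays)
    pvalues = np.asarray(res.pvalue, dtype=float)
    return TukeyResult(
        group_means=np.array([g.mean() for g in arrays]),
        pvalues=pvalues,
        reject=pvalues < alpha,
        alpha=alpha,
    )


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (q in [0, 100]) of a 1-D sample."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty sample")
    if not 0 <= q <= 100:
        raise ValueError("q must lie in [0, 100]")
    rank = int(np.ceil(q / 100.0 * values.size))
    return float(values[max(rank, 1) - 1])
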