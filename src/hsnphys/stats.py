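"""Ordinal embryo-stage summaries and the Wilcoxon Mann-Whitney rank-sum test.

Freshly laid C. elegans embryos are staged into seven ordinal categories
(1-8 cell through hatched L1); retention in the uterus shifts the laid-stage
distribution toward later categories, so genotype comparisons reduce to a
two-sample location test on heavily tied ordinal data.

The rank-sum test here computes the exact two-sided p-value by enumerating
the permutation distribution of the rank sum (midranks for ties) whenever
both groups are small, and falls back to the tie-corrected normal
approximation with continuity correction otherwise. Exactness under ties is
the reason this is implemented directly rather than delegated: common
implementations either forbid ties in exact mode or silently approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Literal, Sequence

import numpy as np
from scipy import stats as _st

from .errors import InputError

__all__ = [
    "STAGE_CATEGORIES",
    "StageDistribution",
    "RankSumResult",
    "stage_scores",
    "rank_sum_test",
    "compare_stage_distributions",
]

STAGE_CATEGORIES: tuple[str, ...] = (
    "1-8 cell",
    "9-25 cell",
    ">26 cell pre-morphogenesis",
    "comma",
    "two-fold",
    "three-fold",
    "hatched/L1",
)

EXACT_CUTOFF = 10  # per-group size at or below which the exact test is used


@dataclass(frozen=True)
class StageDistribution:
    """Counts of embryos over the seven ordinal stage categories."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (len(STAGE_CATEGORIES),):
            raise InputError(f"expected {len(STAGE_CATEGORIES)} categories, got shape {c.shape}")
        if np.any(c < 0):
            raise InputError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    p_two_sided: float
    method: Literal["exact", "normal-approximation"]
    n1: int
    n2: int


def stage_scores(dist: StageDistribution) -> np.ndarray:
    """Expand category counts into a vector of ordinal codes 1..7."""
    return np.repeat(np.arange(1, len(STAGE_CATEGORIES) + 1), dist.counts)


def _exact_p(ranks2: np.ndarray, n1: int, obs_dev2: int) -> float:
    """Exact two-sided p for the rank-sum statistic by enumeration.

    ``ranks2`` are doubled midranks (integers even with .5 ties). The
    permutation distribution of the group-1 rank sum is built by dynamic
    programming over items — an exact, tie-respecting equivalent of
    enumerating all C(n, n1) group labelings. Two-sided p is the proportion
    of labelings whose |U - n1*n2/2| is at least the observed deviation.
    """
    n = ranks2.size
    total_sum = int(ranks2.sum())
    # counts[k, s] = number of k-subsets of the first i items with doubled
    # rank sum s
    counts = np.zeros((n1 + 1, total_sum + 1), dtype=object)
    counts[0, 0] = 1
    for r in ranks2:
        r = int(r)
        counts[1:, r:] = counts[1:, r:] + counts[:-1, : total_sum + 1 - r]
    dist = counts[n1]
    n2 = n - n1
    # doubled U = doubled rank sum - n1(n1+1); doubled mean of U = n1*n2
    s_vals = np.arange(total_sum + 1)
    dev2 = np.abs((s_vals - n1 * (n1 + 1)) - n1 * n2)
    favorable = sum(int(c) for c, d in zip(dist, dev2) if c and d >= obs_dev2)
    return favorable / comb(n, n1)


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["auto", "exact", "normal"] = "auto",
) -> RankSumResult:
    """Two-sided Wilcoxon Mann-Whitney test with midranks for ties.

    ``auto`` uses exact enumeration when both groups have at most
    ``EXACT_CUTOFF`` observations, otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n1, n2 = xv.size, yv.size
    if n1 == 0 or n2 == 0:
        raise InputError("both groups must be non-empty")

    pooled = np.concatenate([xv, yv])
    ranks = _st.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if method == "auto":
        method = "exact" if max(n1, n2) <= EXACT_CUTOFF else "normal"

    if method == "exact":
        ranks2 = np.rint(2.0 * ranks).astype(int)
        obs_dev2 = int(round(abs(2.0 * (u1 - mu))))
        p = _exact_p(ranks2, n1, obs_dev2)
        used = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0  # all observations tied: no evidence either way
        else:
            z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
            z = max(z, 0.0)
            p = float(min(1.0, 2.0 * _st.norm.sf(z)))
        used = "normal-approximation"

    return RankSumResult(
        u_statistic=float(u1),
        p_two_sided=float(min(max(p, 0.0), 1.0)),
        method=used,
        n1=n1,
        n2=n2,
    )


def compare_stage_distributions(
    d1: StageDistribution,
    d2: StageDistribution,
    method: Literal["auto", "exact", "normal"] = "auto",
) -> RankSumResult:
    """Rank-sum comparison of two stage-count distributions (per embryo)."""
    if d1.total == 0 or d2.total == 0:
        raise InputError("both distributions must contain embryos")
    return rank_sum_test(stage_scores(d1), stage_scores(d2), method=method)
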