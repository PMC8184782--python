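"""Resampling and rank statistics for replicate-level comparisons.

Two tests live here.  The replicate-mean permutation test treats the
time-averaged metric of each independent simulation as a single exchangeable
observation and compares two constructs by the absolute difference of group
means, against the relabelling null.  The exact Mann–Whitney test compares
small specimen groups (e.g. per-mouse lesion scores) by enumerating rank
assignments, with mid-ranks for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "PermutationResult",
    "RankTestResult",
    "replicate_mean_permutation_test",
    "mann_whitney_exact",
]

#: Exhaustive enumeration is auto-enabled when the number of distinct group
#: relabellings C(n1+n2, n1) does not exceed this cap.  The cap covers the
#: 10-vs-10 replicate design (184,756 assignments) comfortably.
EXHAUSTIVE_CAP = 1_000_000

# Relative guard when counting null statistics >= observed: assignments that
# are analytically tied with the observed statistic must count even if float
# summation order perturbs them by an ulp.
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    p_value: float
    n_x: int
    n_y: int
    exact: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_statistic <= self.n_x * self.n_y:
            raise ValueError("U outside [0, n1*n2]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value must lie in (0, 1]")


@lru_cache(maxsize=8)
def _assignment_indices(n1: int, n2: int) -> np.ndarray:
    """All C(n1+n2, n1) index subsets of the pooled sample, as an int matrix."""
    return np.array(list(combinations(range(n1 + n2), n1)), dtype=np.intp)


def _abs_mean_diffs(pooled: np.ndarray, idx: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """|mean(group A) − mean(group B)| for each row of subset indices."""
    sums_a = pooled[idx].sum(axis=1)
    total = pooled.sum()
    return np.abs(sums_a / n1 - (total - sums_a) / n2)


def replicate_mean_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_permutations: int = 1_000_000,
    seed: int | None = None,
    exhaustive: bool | None = None,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> PermutationResult:
    """Two-sided permutation test on per-replicate mean values.

    The statistic is ``|mean(a) − mean(b)|``; the null is built by relabelling
    the pooled values into groups of the original sizes.

    Modes
    -----
    exhaustive (default when C(n1+n2, n1) <= *exhaustive_cap*)
        Every distinct relabelling is enumerated once and
        ``p = #(null >= observed) / total`` — the identity labelling is one of
        the assignments, so p is never zero.
    sampled
        *n_permutations* relabellings are drawn uniformly with replacement and
        ``p = (#(null >= observed) + 1) / (n_permutations + 1)``; a seed is
        mandatory for reproducibility.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicate means")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite replicate means")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    n_distinct = math.comb(n1 + n2, n1)
    if exhaustive is None:
        exhaustive = n_distinct <= exhaustive_cap
    elif exhaustive and n_distinct > exhaustive_cap:
        raise ValueError(
            f"C({n1 + n2},{n1}) = {n_distinct} assignments exceed the cap "
            f"{exhaustive_cap}; use sampled mode or raise the cap"
        )

    observed = float(abs(a.mean() - b.mean()))
    threshold = observed - _TIE_EPS * (1.0 + observed)

    if exhaustive:
        idx = _assignment_indices(n1, n2)
        diffs = _abs_mean_diffs(pooled, idx, n1, n2)
        count = int(np.count_nonzero(diffs >= threshold))
        return PermutationResult(observed, count / n_distinct, n_distinct, True, None)

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if seed is None:
        raise ValueError("sampled mode requires a seed")
    rng = np.random.default_rng(seed)
    count = 0
    remaining = n_permutations
    chunk = 200_000
    while remaining > 0:
        m = min(chunk, remaining)
        # uniform random relabelling: first n1 slots of a random permutation
        order = np.argsort(rng.random((m, n1 + n2)), axis=1)[:, :n1]
        diffs = _abs_mean_diffs(pooled, order, n1, n2)
        count += int(np.count_nonzero(diffs >= threshold))
        remaining -= m
    p = (count + 1) / (n_permutations + 1)
    return PermutationResult(observed, p, n_permutations, False, seed)


def mann_whitney_exact(x: np.ndarray, y: np.ndarray) -> RankTestResult:
    """Two-sided Mann–Whitney U test, exact for small samples.

    For n1 + n2 <= 20 the p-value is exact: all C(n1+n2, n1) assignments of
    the pooled mid-ranks to the first group are enumerated and the two-sided
    p is the proportion whose U deviates from the null mean n1*n2/2 at least
    as far as the observed U.  Ties are handled by mid-ranks, which the
    enumeration honours automatically.  Larger samples use the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # mid-ranks for ties
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if n1 + n2 <= 20:
        idx = _assignment_indices(n1, n2)
        rank_sums = ranks[idx].sum(axis=1)
        u_null = rank_sums - n1 * (n1 + 1) / 2.0
        dev_obs = abs(u1 - n1 * n2 / 2.0)
        dev_null = np.abs(u_null - n1 * n2 / 2.0)
        count = int(np.count_nonzero(dev_null >= dev_obs - 1e-9))
        return RankTestResult(u1, count / len(idx), n1, n2, True)

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return RankTestResult(float(res.statistic), float(res.pvalue), n1, n2, False)
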