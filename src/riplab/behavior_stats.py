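"""Courtship-conditioning memory statistics.

In the courtship-suppression paradigm a male is observed with a previously
mated (non-receptive) female for a fixed window (300 s by convention).  The
courtship index (CI) is the percentage of the window spent courting; the
learning index LI = (CIn - CIexp) / CIn * 100 measures the relative
suppression of courtship in trained males (CIexp) against naive controls
(CIn), each arm averaged over two independent samples of males.

Group differences are assessed with a sampled randomization test: group
labels are permuted over the pooled per-male courtship indices and the
probability of rejecting the null, alpha_R, is estimated directly from the
permutation distribution.  Whenever the number of distinct label
assignments does not exceed the requested permutation count the test is
exhaustive and alpha_R is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np

from .errors import ConfigurationError, InputError, UndefinedIndexError

__all__ = [
    "CourtshipObservation",
    "LearningIndexResult",
    "RandomizationResult",
    "courtship_index",
    "learning_index",
    "merge_bouts",
    "randomization_test",
]

Sides = Literal["one-sided", "two-sided"]
Statistic = Literal["mean-difference", "learning-index"]


@dataclass
class CourtshipObservation:
    """One male's courtship bouts within a fixed observation window."""

    male_id: str
    group: str
    bouts: list[tuple[float, float]]
    observation_s: float = 300.0

    def __post_init__(self) -> None:
        for start, end in self.bouts:
            if not (0.0 <= start < end <= self.observation_s):
                raise InputError(
                    f"bout ({start}, {end}) outside [0, {self.observation_s}] "
                    f"for male {self.male_id!r}"
                )


@dataclass(frozen=True)
class LearningIndexResult:
    """Learning index with the naive and trained mean courtship indices (all %)."""

    LI: float
    CIn: float
    CIexp: float


@dataclass(frozen=True)
class RandomizationResult:
    statistic_observed: float
    n_permutations: int
    alpha_R: float
    sides: Sides
    seed: int | None = None
    exhaustive: bool = field(default=False)


def merge_bouts(bouts: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or touching intervals so time is never double-counted."""
    if not bouts:
        return []
    ordered = sorted(bouts)
    merged = [list(ordered[0])]
    for start, end in ordered[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def courtship_index(obs: CourtshipObservation) -> float:
    """CI: percentage of the observation window spent courting, in [0, 100]."""
    total = sum(e - s for s, e in merge_bouts(obs.bouts))
    return 100.0 * total / obs.observation_s


def learning_index(
    naive_cis: Sequence[Sequence[float]],
    trained_cis: Sequence[Sequence[float]],
) -> LearningIndexResult:
    """LI from two independent naive samples and two independent trained samples.

    CIn (CIexp) is the mean of the two naive (trained) sample means; then
    LI = (CIn - CIexp) / CIn * 100.
    """
    if not naive_cis or any(len(s) == 0 for s in naive_cis):
        raise InputError("every naive sample must be non-empty")
    if not trained_cis or any(len(s) == 0 for s in trained_cis):
        raise InputError("every trained sample must be non-empty")
    cin = float(np.mean([np.mean(s) for s in naive_cis]))
    ciexp = float(np.mean([np.mean(s) for s in trained_cis]))
    if cin == 0:
        raise UndefinedIndexError("LI undefined: naive mean courtship index is 0")
    li = (cin - ciexp) / cin * 100.0
    return LearningIndexResult(LI=li, CIn=cin, CIexp=ciexp)


def _li_statistic(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    # LI of arm A (naive) vs arm B (trained); permutations can make mean_a 0,
    # in which case the statistic is +/-inf and still ordered correctly.
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (mean_a - mean_b) / mean_a * 100.0
    return out


def randomization_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    statistic: Statistic = "mean-difference",
    sides: Sides = "two-sided",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> RandomizationResult:
    """Sampled randomization test on per-male courtship indices.

    Labels are permuted over the pooled values.  alpha_R is the probability
    of a statistic as or more extreme than observed: |stat| for two-sided,
    signed stat (upper tail of the statistic as computed) for one-sided.
    Sampled runs use the (b + 1) / (m + 1) estimator so alpha_R is never 0;
    when the number of distinct assignments of pooled values to arm A is at
    most ``n_permutations`` the assignments are enumerated exhaustively and
    alpha_R = b / m is exact.

    For ``statistic="learning-index"`` arm A is the pooled naive males, arm B
    the pooled trained males, and LI is recomputed for every permutation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    if n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    if statistic not in ("mean-difference", "learning-index"):
        raise ConfigurationError(f"unknown statistic {statistic!r}")
    if sides not in ("one-sided", "two-sided"):
        raise ConfigurationError(f"unknown sides {sides!r}")

    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size
    total = pooled.sum()

    def stats_from_sum_a(sum_a: np.ndarray) -> np.ndarray:
        mean_a = sum_a / n_a
        mean_b = (total - sum_a) / (n - n_a)
        if statistic == "mean-difference":
            return mean_a - mean_b
        return _li_statistic(mean_a, mean_b)

    observed = float(stats_from_sum_a(np.array([a.sum()]))[0])

    n_assignments = math.comb(n, n_a)
    exhaustive = n_assignments <= n_permutations
    if exhaustive:
        sums = np.fromiter(
            (pooled[list(idx)].sum() for idx in combinations(range(n), n_a)),
            dtype=float,
            count=n_assignments,
        )
        perm_stats = stats_from_sum_a(sums)
        m = n_assignments
    else:
        rng = np.random.default_rng(seed)
        # Row-wise random permutations via argsort of iid uniforms; arm A is
        # the first n_a entries of each shuffled row.
        order = np.argsort(rng.random((n_permutations, n)), axis=1)
        sums = pooled[order[:, :n_a]].sum(axis=1)
        perm_stats = stats_from_sum_a(sums)
        m = n_permutations

    tol = 1e-12 * max(1.0, abs(observed))  # ties at the observed value count
    if sides == "two-sided":
        extreme = np.abs(perm_stats) >= abs(observed) - tol
    else:
        extreme = perm_stats >= observed - tol
    n_extreme = int(np.count_nonzero(extreme))

    alpha = n_extreme / m if exhaustive else (n_extreme + 1) / (m + 1)
    return RandomizationResult(
        statistic_observed=observed,
        n_permutations=m,
        alpha_R=float(alpha),
        sides=sides,
        seed=seed,
        exhaustive=exhaustive,
    )
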