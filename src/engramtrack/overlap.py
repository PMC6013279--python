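"""Exact overlap statistics for longitudinal neuronal-ensemble tracking.

The similarity between the active-cell sets of two imaging sessions is the
Jaccard coefficient ``J = c / (a + b - c)``, where ``a`` and ``b`` are the
numbers of active cells on the two sessions and ``c`` the number of cells
active on both.  Its chance level is assessed against an exact combinatorial
null: holding ``a``, ``b`` and the size ``t`` of the animal's active-cell
pool fixed, and treating the second session's active set as a uniformly
random ``b``-subset of the pool, the co-active count follows the
hypergeometric law

    P(c) = C(a, c) * C(t - a, b - c) / C(t, b)

on the support ``max(0, a + b - t) <= c <= min(a, b)``.  Because ``J`` is
strictly increasing in ``c`` at fixed ``(a, b)``, the upper tail in ``c``
equals the upper tail in ``J``; the reported p-value is the inclusive tail
``P(C >= c_obs)``.  All binomial coefficients are evaluated through
log-gamma so pools of thousands of cells do not overflow.

Per-animal p-values for a given session pair are combined across the cohort
with Fisher's method (-2 * sum(log p) ~ chi-square with 2k df) and assessed
at a Bonferroni-adjusted alpha (alpha / number-of-session-pairs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2

__all__ = [
    "OverlapTest",
    "CombinedResult",
    "jaccard",
    "overlap_test",
    "null_distribution",
    "overlap_pvalue",
    "fisher_combine",
    "bonferroni_alpha",
    "normalize_similarity",
    "reactivation_score",
    "chance_normalized_reactivation",
]


@dataclass(frozen=True)
class OverlapTest:
    """One pairwise ensemble-overlap test: counts, similarity and p-value.

    Attributes
    ----------
    a, b : int
        Numbers of active cells on the two sessions.
    c : int
        Number of co-active cells.
    t : int
        Size of the animal's active-cell pool (the null universe).
    jaccard : float
        Similarity index ``c / (a + b - c)`` (0 when both sets are empty).
    p_value : float
        Inclusive upper-tail probability ``P(C >= c)`` under the
        hypergeometric null.
    """

    a: int
    b: int
    c: int
    t: int
    jaccard: float
    p_value: float


@dataclass(frozen=True)
class CombinedResult:
    """Fisher-combined evidence for one session pair across animals."""

    p_values: tuple
    statistic: float
    df: int
    p_value: float

    def significant(self, alpha: float = 0.05, n_tests: int = 1) -> bool:
        return self.p_value < bonferroni_alpha(alpha, n_tests)


def _validate_counts(a: int, b: int, t: int) -> None:
    for name, v in (("a", a), ("b", b), ("t", t)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if t < 1:
        raise ValueError(f"pool size t must be >= 1, got {t}")
    if a > t or b > t:
        raise ValueError(f"a and b cannot exceed the pool size t (a={a}, b={b}, t={t})")


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard similarity |A∩B| / |A∪B| between two active-cell sets.

    Both sets empty is degenerate; by convention J = 0 with a warning.
    """
    sa, sb = set(set_a), set(set_b)
    union = len(sa | sb)
    if union == 0:
        warnings.warn("Jaccard of two empty sets: defined as 0", stacklevel=2)
        return 0.0
    return len(sa & sb) / union


def _support(a: int, b: int, t: int) -> np.ndarray:
    return np.arange(max(0, a + b - t), min(a, b) + 1)


def _log_pmf(a: int, b: int, t: int, c: np.ndarray) -> np.ndarray:
    """log P(c) = log[ C(a,c) C(t-a, b-c) / C(t,b) ] via log-gamma."""

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return logC(a, c) + logC(t - a, b - c) - logC(t, b)


def null_distribution(a: int, b: int, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the co-active count ``c``.

    Returns ``(support, pmf)`` where ``support`` runs from
    ``max(0, a + b - t)`` to ``min(a, b)`` and ``pmf`` sums to 1.
    """
    _validate_counts(a, b, t)
    c = _support(a, b, t)
    return c, np.exp(_log_pmf(a, b, t, c))


def overlap_pvalue(a: int, b: int, c_obs: int, t: int) -> float:
    """Inclusive upper-tail probability ``P(C >= c_obs)`` under the null.

    Computed as a log-sum-exp over the tail of the log pmf; exact up to
    floating point for pools of any realistic size.
    """
    _validate_counts(a, b, t)
    lo, hi = max(0, a + b - t), min(a, b)
    if c_obs < lo or c_obs > hi:
        raise ValueError(
            f"observed overlap c={c_obs} outside the valid range [{lo}, {hi}] "
            f"for a={a}, b={b}, t={t}"
        )
    tail = np.arange(c_obs, hi + 1)
    p = float(np.exp(logsumexp(_log_pmf(a, b, t, tail))))
    return min(p, 1.0)


def overlap_test(set_a: Iterable, set_b: Iterable, pool_size: int) -> OverlapTest:
    """Full overlap test between two sessions' active-cell sets.

    When either session has no active cells the similarity is 0 and the
    p-value 1 (the tail covers the whole support), with a warning.
    """
    sa, sb = set(set_a), set(set_b)
    a, b, c = len(sa), len(sb), len(sa & sb)
    _validate_counts(a, b, pool_size)
    if a == 0 or b == 0:
        warnings.warn(
            "session with zero active cells: J set to 0 and p to 1", stacklevel=2
        )
        return OverlapTest(a=a, b=b, c=0, t=pool_size, jaccard=0.0, p_value=1.0)
    j = c / (a + b - c)
    return OverlapTest(
        a=a, b=b, c=c, t=pool_size, jaccard=j,
        p_value=overlap_pvalue(a, b, c, pool_size),
    )


def fisher_combine(p_values: Sequence[float]) -> CombinedResult:
    """Combine per-animal p-values for one session pair by Fisher's method.

    X = -2 * sum(ln p_i) is referred to a chi-square distribution with
    2k degrees of freedom.  A single p-value is returned unchanged.
    """
    ps = [float(p) for p in p_values]
    if not ps:
        raise ValueError("fisher_combine requires at least one p-value")
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError(
                f"p-values must lie in (0, 1]; got {p} (floor zero p-values first)"
            )
    x = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    combined = float(chi2.sf(x, df)) if len(ps) > 1 else ps[0]
    return CombinedResult(p_values=tuple(ps), statistic=x, df=df, p_value=combined)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Family-wise adjusted threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


@dataclass(frozen=True)
class NormalizedSimilarity:
    """Two-stage normalised similarity indices (see ``normalize_similarity``)."""

    r2_r1: np.ndarray
    r2_19: np.ndarray
    scale: float
    included: np.ndarray = field(repr=False)


def normalize_similarity(
    j_r2_r1: Sequence[float],
    j_r2_19: Sequence[float],
    j_r2_c1: Sequence[float],
) -> NormalizedSimilarity:
    """Normalise the retention similarity indices against the control index.

    Stage 1 divides each animal's J(R2,R1) and J(R2,19) by that animal's
    J(R2,C1), removing the non-specific similarity component and
    craniotomy-quality differences.  Stage 2 rescales all stage-1 values by
    the single cohort constant s = mean(stage-1 values) / mean(raw values),
    pulling the normalised indices back onto the raw scale.  Animals with
    J(R2,C1) = 0 are excluded with a warning.
    """
    r2_r1 = np.asarray(j_r2_r1, dtype=float)
    r2_19 = np.asarray(j_r2_19, dtype=float)
    c1 = np.asarray(j_r2_c1, dtype=float)
    if not (r2_r1.shape == r2_19.shape == c1.shape):
        raise ValueError("all three index arrays must have the same length")
    included = c1 > 0
    if not included.all():
        warnings.warn(
            f"excluding {int((~included).sum())} animal(s) with J(R2,C1) = 0 "
            "from similarity normalisation",
            stacklevel=2,
        )
    if not included.any():
        raise ValueError("no animal has a positive J(R2,C1); cannot normalise")
    stage1_r1 = r2_r1[included] / c1[included]
    stage1_19 = r2_19[included] / c1[included]
    raw_mean = float(np.concatenate([r2_r1[included], r2_19[included]]).mean())
    stage1_mean = float(np.concatenate([stage1_r1, stage1_19]).mean())
    if raw_mean <= 0:
        raise ValueError("mean raw similarity is zero; cannot rescale")
    scale = stage1_mean / raw_mean
    return NormalizedSimilarity(
        r2_r1=stage1_r1 / scale,
        r2_19=stage1_19 / scale,
        scale=scale,
        included=included,
    )


def reactivation_score(ref_active_set: Iterable, r2_active_set: Iterable) -> float:
    """Percentage of reference-session active cells that reactivate on R2.

    100 * |R2 ∩ ref| / |ref|; the reference set (session 19 or R1 actives)
    must be non-empty.
    """
    ref, r2 = set(ref_active_set), set(r2_active_set)
    if not ref:
        raise ValueError("reference active set is empty")
    return 100.0 * len(r2 & ref) / len(ref)


def chance_normalized_reactivation(
    score: float,
    a_ref: int,
    a_r2: int,
    t: int,
    convention: str = "per_reference",
) -> float:
    """Reactivation score normalised to its chance level.

    ``convention="per_reference"`` (default) treats the score as the
    fraction of reference cells reactivating and divides by the chance
    probability a_R2 / t that any pool cell is active on R2, so data at the
    hypergeometric expectation normalise to exactly 1.

    ``convention="literal"`` divides the raw percentage score by the product
    (a_ref / t) * (a_R2 / t).  This reading mixes a percentage with a
    product of fractions and does not normalise chance-level data to 1; it
    is provided for comparability only.
    """
    if t <= 0:
        raise ValueError(f"pool size t must be positive, got {t}")
    if a_ref <= 0:
        raise ValueError(f"reference active count must be positive, got {a_ref}")
    if a_r2 < 0 or a_ref > t or a_r2 > t:
        raise ValueError(f"invalid counts a_ref={a_ref}, a_r2={a_r2}, t={t}")
    if convention == "per_reference":
        chance = a_r2 / t
        if chance == 0:
            raise ValueError("chance reactivation is zero (no cells active on R2)")
        return (score / 100.0) / chance
    if convention == "literal":
        chance = (a_ref / t) * (a_r2 / t)
        if chance == 0:
            raise ValueError("chance reactivation is zero")
        return score / chance
    raise ValueError(f"unknown convention {convention!r}")
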