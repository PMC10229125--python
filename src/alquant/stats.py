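"""Label-shuffle permutation statistics, Bonferroni control, and the
rank-sum fallback.

Group differences are evaluated with a permutation test on the difference of
group means: observations from both exposure groups are pooled and randomly
reassigned into two groups of the original sizes; the two-tailed p-value is
the fraction of shuffles whose absolute mean difference equals or exceeds
the absolute observed difference (ties count as extreme, and no +1
small-sample correction is applied).  The Monte-Carlo default is 10,000
shuffles; an exact mode enumerates every label assignment and serves as the
Monte-Carlo oracle.  Significance is assessed at alpha = 0.05 divided by the
number of comparisons (Bonferroni).  The Mann-Whitney U (Wilcoxon rank-sum)
test is provided as the distribution-free alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata

from .errors import ParameterError

EXACT_ENUM_LIMIT = 200_000


@dataclass
class PermResult:
    """Outcome of a two-group permutation test on the difference of means."""

    obs_diff: float
    n_perm: int
    n_extreme: int
    p_two_tailed: float
    alpha: float = 0.05
    m_comparisons: int = 1
    significant: bool = False
    exact: bool = False
    seed: int | None = None


def _check_groups(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("groups must be finite")
    return a, b


def perm_test(
    a,
    b,
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
    m_comparisons: int = 1,
) -> PermResult:
    """Monte-Carlo permutation test on mean(a) - mean(b).

    Each of the ``n_perm`` iterations shuffles the pooled labels without
    replacement, preserving the group sizes; iterations are independent
    draws.  Two-tailed p = n_extreme / n_perm with ties counting as extreme.
    Reproducible for a fixed ``seed``.
    """
    a, b = _check_groups(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    obs = float(a.mean() - b.mean())

    # vectorized shuffles: argsort of iid uniforms is a uniform permutation
    n_extreme = 0
    block = 2000
    total_mean = pooled.mean()
    for start in range(0, n_perm, block):
        m = min(block, n_perm - start)
        keys = rng.random((m, n))
        order = np.argpartition(keys, na - 1, axis=1)[:, :na]
        mean_a = pooled[order].mean(axis=1)
        # mean(b) from the pooled total, avoiding a second gather
        mean_b = (total_mean * n - mean_a * na) / (n - na)
        diffs = mean_a - mean_b
        n_extreme += int(np.sum(np.abs(diffs) >= abs(obs) - 1e-12))
    p = n_extreme / n_perm
    return PermResult(
        obs_diff=obs,
        n_perm=n_perm,
        n_extreme=n_extreme,
        p_two_tailed=p,
        alpha=alpha,
        m_comparisons=m_comparisons,
        significant=p < bonferroni(alpha, m_comparisons),
        exact=False,
        seed=seed,
    )


def perm_test_exact(
    a,
    b,
    alpha: float = 0.05,
    m_comparisons: int = 1,
) -> PermResult:
    """Exact permutation test: enumerate every assignment of labels.

    Restricted to C(|a|+|b|, |a|) <= 200,000 assignments.
    """
    a, b = _check_groups(a, b)
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    n_assign = comb(n, na)
    if n_assign > EXACT_ENUM_LIMIT:
        raise ParameterError(
            f"{n_assign} assignments exceed the exact-mode bound of {EXACT_ENUM_LIMIT}"
        )
    obs = float(a.mean() - b.mean())
    idx = np.fromiter(
        (i for c in combinations(range(n), na) for i in c), dtype=np.intp
    ).reshape(n_assign, na)
    mean_a = pooled[idx].mean(axis=1)
    mean_b = (pooled.sum() - mean_a * na) / (n - na)
    diffs = mean_a - mean_b
    n_extreme = int(np.sum(np.abs(diffs) >= abs(obs) - 1e-12))
    p = n_extreme / n_assign
    return PermResult(
        obs_diff=obs,
        n_perm=n_assign,
        n_extreme=n_extreme,
        p_two_tailed=p,
        alpha=alpha,
        m_comparisons=m_comparisons,
        significant=p < bonferroni(alpha, m_comparisons),
        exact=True,
    )


def bonferroni(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ParameterError("number of comparisons must be >= 1")
    return alpha / m


def ranksum_test(a, b, method: str = "auto") -> float:
    """Two-tailed Mann-Whitney U (Wilcoxon rank-sum) p-value.

    Exact by enumeration of label assignments over midranks when
    min(|a|, |b|) <= 8 (ties allowed; the two-tailed rule counts assignments
    whose |U - n1 n2 / 2| is at least the observed deviation); normal
    approximation with tie correction otherwise.  ``method`` forces one
    branch ("exact" / "approx").
    """
    a, b = _check_groups(a, b)
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    center = na * nb / 2.0

    def u_stat(rank_a_sum: float) -> float:
        return rank_a_sum - na * (na + 1) / 2.0

    obs_dev = abs(u_stat(float(ranks[:na].sum())) - center)

    if method not in ("auto", "exact", "approx"):
        raise ParameterError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and min(na, nb) <= 8):
        n = na + nb
        if comb(n, na) > EXACT_ENUM_LIMIT:
            raise ParameterError("too many assignments for exact rank-sum enumeration")
        idx = np.fromiter(
            (i for c in combinations(range(n), na) for i in c), dtype=np.intp
        ).reshape(-1, na)
        devs = np.abs(u_stat(ranks[idx].sum(axis=1)) - center)
        return float(np.mean(devs >= obs_dev - 1e-12))

    # normal approximation with tie correction
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var_u = na * nb / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return 1.0
    from scipy.stats import norm

    z = (obs_dev - 0.5) / np.sqrt(var_u)  # continuity-corrected
    return float(min(2 * norm.sf(max(z, 0.0)), 1.0))
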