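"""Within-cluster permutation reference machinery.

The null distribution of S = sum_i v_i sum_j w_ij zeta_ij re-assigns the
treatment labels independently within each cluster, keeping the per-cluster
group sizes w_i fixed — the permutation space is the product of the
per-cluster combination sets, of size prod_i C(n_i, w_i).

This module provides the observed statistic, the exact permutation
moments, the asymptotic-normal mid-p, uniform sampling from the
permutation space, the Monte Carlo mid-p estimator, and a brute-force
exact-enumeration mid-p (the ground-truth oracle on small spaces).

All mid-p-values target  mid-p = P(S > s_obs) + 1/2 P(S = s_obs)
(upper side); the lower side replaces ">" by "<". Equality of statistics
is decided with an absolute tolerance of 1e-9 on the statistic scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm

from .scores import ScoreSet

__all__ = [
    "TestResult",
    "EQ_TOL",
    "observed_statistic",
    "permutation_moments",
    "an_midp",
    "sample_within_cluster_permutation",
    "mcp_midp",
    "exact_distribution",
    "exact_midp",
    "permutation_space_size",
]

#: absolute tolerance for deciding S_b == S_obs on the statistic scale
EQ_TOL = 1e-9


@dataclass
class TestResult:
    """Result of one clustered rank test, possibly under several engines."""

    test: str
    s_obs: float
    perm_mean: float
    perm_var: float
    #: engine name -> {"upper": p, "lower": p, "two_sided": p}
    midp: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "s_obs": self.s_obs,
            "perm_mean": self.perm_mean,
            "perm_var": self.perm_var,
            "midp": self.midp,
            "diagnostics": self.diagnostics,
        }


def observed_statistic(scores: ScoreSet) -> float:
    """S = sum_i v_i sum_j w_ij zeta_ij evaluated at the observed arms."""
    return float(np.sum(scores.tilt_coefficients() * scores.arm))


def permutation_moments(scores: ScoreSet) -> tuple[float, float]:
    """Exact mean and variance of S under within-cluster permutation.

    mean = sum_i v_i (w_i/n_i) sum_j w_ij ;
    var  = sum_i v_i^2 [w_i(n_i-w_i) / (n_i(n_i-1))] sum_j (w_ij - wbar_i)^2.

    The variance uses within-cluster deviations, which coincides with the
    plain sum of squares once scores are centered; clusters with n_i = 1
    or w_i in {0, n_i} contribute nothing.
    """
    n, w1, v = scores.n_i, scores.w_i, scores.v
    tot = np.bincount(scores.cluster, weights=scores.scores, minlength=scores.n_clusters)
    mean = float(np.sum(v * (w1 / n) * tot))
    dev = scores.scores - (tot / n)[scores.cluster]
    ss = np.bincount(scores.cluster, weights=dev * dev, minlength=scores.n_clusters)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(n > 1, w1 * (n - w1) / (n * np.maximum(n - 1, 1)), 0.0)
    var = float(np.sum(v * v * factor * ss))
    return mean, var


def an_midp(scores: ScoreSet, side: str = "upper") -> float:
    """Asymptotic-normal mid-p: Phi complement of the standardized S.

    No continuity correction — the normal limit approximates the mid-p
    directly.
    """
    mean, var = permutation_moments(scores)
    if var <= 0:
        raise ValueError("degenerate permutation distribution (zero variance)")
    z = (observed_statistic(scores) - mean) / math.sqrt(var)
    upper = float(norm.sf(z))
    return _sided(upper, 1.0 - upper, side)


def _sided(upper: float, lower: float, side: str) -> float:
    if side == "upper":
        return upper
    if side == "lower":
        return lower
    if side in ("two-sided", "two_sided"):
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown side {side!r}")


def permutation_space_size(scores: ScoreSet) -> int:
    return math.prod(math.comb(int(n), int(w))
                     for n, w in zip(scores.n_i, scores.w_i))


def sample_within_cluster_permutation(scores: ScoreSet,
                                      rng: np.random.Generator) -> np.ndarray:
    """One uniform draw of arms: within each cluster exactly w_i subjects
    get zeta = 1, clusters independently."""
    arm = np.zeros(scores.scores.size, dtype=np.int8)
    for i in range(scores.n_clusters):
        idx = np.flatnonzero(scores.cluster == i)
        chosen = rng.choice(idx, size=int(scores.w_i[i]), replace=False)
        arm[chosen] = 1
    return arm


def _permuted_statistics(scores: ScoreSet, B: int,
                         rng: np.random.Generator) -> np.ndarray:
    """B draws of S under within-cluster permutation, vectorized.

    Per cluster, ranks of i.i.d. uniforms give a uniform random subset of
    size w_i; the per-cluster treated-score sums accumulate over clusters.
    """
    s = np.zeros(B)
    a = scores.tilt_coefficients()
    for i in range(scores.n_clusters):
        idx = np.flatnonzero(scores.cluster == i)
        w1 = int(scores.w_i[i])
        if w1 == 0:
            continue
        ai = a[idx]
        if w1 == idx.size:
            s += ai.sum()
            continue
        u = rng.random((B, idx.size))
        part = np.argpartition(u, w1 - 1, axis=1)[:, :w1]
        s += ai[part].sum(axis=1)
    return s


def mcp_midp(scores: ScoreSet, B: int, rng: np.random.Generator,
             side: str = "upper", return_draws: bool = False):
    """Monte Carlo permutation mid-p:

    mid-p = B^{-1} ( sum_b I(S_b > S_obs) + 1/2 sum_b I(S_b = S_obs) ).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    s_obs = observed_statistic(scores)
    s_b = _permuted_statistics(scores, int(B), rng)
    eq = np.abs(s_b - s_obs) <= EQ_TOL
    upper = float((np.sum(s_b > s_obs + EQ_TOL) + 0.5 * eq.sum()) / B)
    lower = float((np.sum(s_b < s_obs - EQ_TOL) + 0.5 * eq.sum()) / B)
    p = _sided(upper, lower, side)
    if return_draws:
        return p, s_b
    return p


def _cluster_choice_sums(a: np.ndarray, w1: int) -> np.ndarray:
    """Sums of a over every size-w1 subset, in lexicographic subset order."""
    return np.array([sum(c) for c in combinations(a.tolist(), w1)])


def exact_distribution(scores: ScoreSet,
                       max_space: int = 2_000_000) -> np.ndarray:
    """All prod_i C(n_i, w_i) attainable values of S (with multiplicity).

    Clusters are iterated in input order and subsets in lexicographic
    order; the resulting distribution is order-independent.
    """
    space = permutation_space_size(scores)
    if space > max_space:
        raise ValueError(
            f"permutation space {space} exceeds max_space={max_space}; "
            "use the Monte Carlo engine instead")
    a = scores.tilt_coefficients()
    values = np.zeros(1)
    for i in range(scores.n_clusters):
        idx = np.flatnonzero(scores.cluster == i)
        sums = _cluster_choice_sums(a[idx], int(scores.w_i[i]))
        values = (values[:, None] + sums[None, :]).ravel()
    return values


def exact_midp(scores: ScoreSet, side: str = "upper",
               max_space: int = 2_000_000) -> float:
    """Exact mid-p by full enumeration of the within-cluster permutation
    space (the ground-truth oracle for the saddlepoint and Monte Carlo
    engines)."""
    values = exact_distribution(scores, max_space=max_space)
    s_obs = observed_statistic(scores)
    eq = np.abs(values - s_obs) <= EQ_TOL
    B = values.size
    upper = float((np.sum(values > s_obs + EQ_TOL) + 0.5 * eq.sum()) / B)
    lower = float((np.sum(values < s_obs - EQ_TOL) + 0.5 * eq.sum()) / B)
    return _sided(upper, lower, side)
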