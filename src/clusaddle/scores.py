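"""Fixed rank scores for clustered two-sample and paired tests.

Every test handled here is a linear rank statistic

    S = sum_i v_i sum_j w_ij zeta_ij,

where ``w_ij`` is a per-subject score computed once from the observed
outcomes, ``v_i`` a cluster weight, and ``zeta_ij`` the binary treatment
indicator. Under the within-cluster permutation null only the ``zeta_ij``
are random; scores are fixed constants. The constructions:

* ``ds_scores``   — Datta–Satten cluster-adjusted rank-sum scores built
  from between-cluster empirical distribution functions,
* ``wsr_scores``  — clustered Wilcoxon signed-rank scores (mid-ranks of
  absolute paired differences, sign as the "arm"),
* ``survival_scores`` — weighted logrank observed-minus-expected scores
  for right-censored data (logrank / Gehan–Wilcoxon / Prentice–Wilcoxon
  weights).

Ties are handled with mid-ranks; censoring through pooled risk sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .data import ClusteredDataset, PairedClusteredDataset

__all__ = [
    "ScoreSet",
    "midrank",
    "ds_scores",
    "wsr_scores",
    "survival_scores",
    "assemble_scores",
    "build_scores",
    "TESTS",
]

TESTS = ("ds", "wsr", "lr", "gw", "pw")


@dataclass(frozen=True)
class ScoreSet:
    """Fixed scores, arms and cluster weights — the sufficient input to
    every p-value engine.

    Attributes
    ----------
    cluster : int array, subject -> cluster index 0..M-1
    scores : float array, per-subject score w_ij
    arm : 0/1 array, treatment indicator zeta_ij
    v : float array of length M, cluster weights v_i
    test : name of the generating test
    centered : whether scores were mean-centered within clusters
    """

    cluster: np.ndarray
    scores: np.ndarray
    arm: np.ndarray
    v: np.ndarray
    test: str = ""
    centered: bool = False
    tie_policy: str = "midrank"
    n_i: np.ndarray = field(init=False, repr=False)
    w_i: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        cluster = np.asarray(self.cluster, dtype=np.intp)
        scores = np.asarray(self.scores, dtype=float)
        arm = np.asarray(self.arm, dtype=np.int8)
        v = np.asarray(self.v, dtype=float)
        M = v.size
        if cluster.size != scores.size or arm.size != scores.size:
            raise ValueError("cluster, scores and arm must have equal length")
        if not np.isfinite(scores).all():
            raise ValueError("scores must be finite")
        n_i = np.bincount(cluster, minlength=M)
        if (n_i < 1).any():
            raise ValueError("every cluster must contain at least one subject")
        w_i = np.bincount(cluster, weights=arm.astype(float), minlength=M).astype(np.intp)
        object.__setattr__(self, "cluster", cluster)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "arm", arm)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "n_i", n_i)
        object.__setattr__(self, "w_i", w_i)
        if self.centered:
            means = self.cluster_means()
            if np.abs(means * n_i).max() > 1e-8:
                raise ValueError("centered flag set but within-cluster sums are not 0")

    @property
    def n_clusters(self) -> int:
        return int(self.v.size)

    def cluster_means(self) -> np.ndarray:
        tot = np.bincount(self.cluster, weights=self.scores, minlength=self.n_clusters)
        return tot / self.n_i

    def tilt_coefficients(self) -> np.ndarray:
        """a_ij = v_i * w_ij, the per-subject coefficients of S in zeta."""
        return self.v[self.cluster] * self.scores

    def with_arm(self, arm: np.ndarray) -> "ScoreSet":
        return replace(self, arm=np.asarray(arm, dtype=np.int8))


def midrank(values) -> np.ndarray:
    """Mid-ranks (ties get the average of the ranks they span).

    The returned ranks always sum to N(N+1)/2.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("midrank requires a non-empty input")
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"non-finite value at index {bad[0]}")
    return rankdata(values, method="average")


def ds_scores(data: ClusteredDataset) -> ScoreSet:
    """Datta–Satten rank-sum scores.

    For subject (i, j):  w_ij = 1 + 1/2 * sum_{k != i} (F_k(y_ij) + F_k(y_ij^-)),
    with F_k the empirical distribution function of cluster k and F_k(.^-)
    its left limit. Scores lie in [1, M]. With censored data this is
    applied to the observed times, ignoring event indicators.
    """
    M = data.n_clusters
    y = data.y
    # For each cluster k hold its sorted outcomes; evaluate F_k at every y
    # via searchsorted. Sum over all k then subtract the own-cluster term.
    tot_le = np.zeros(y.size)   # sum_k F_k(y)
    tot_lt = np.zeros(y.size)   # sum_k F_k(y^-)
    own_le = np.zeros(y.size)
    own_lt = np.zeros(y.size)
    for k in range(M):
        mask = data.cluster == k
        yk = np.sort(y[mask])
        le = np.searchsorted(yk, y, side="right") / yk.size
        lt = np.searchsorted(yk, y, side="left") / yk.size
        tot_le += le
        tot_lt += lt
        own_le[mask] = le[mask]
        own_lt[mask] = lt[mask]
    w = 1.0 + 0.5 * ((tot_le - own_le) + (tot_lt - own_lt))
    return ScoreSet(data.cluster, w, data.arm, np.ones(M), test="ds")


def wsr_scores(data: PairedClusteredDataset, zero_policy: str = "drop") -> ScoreSet:
    """Clustered Wilcoxon signed-rank scores.

    Scores are the pooled mid-ranks of |D_ij|; the "arm" indicator is
    I(D_ij > 0). ``zero_policy='drop'`` removes exact-zero differences
    before ranking; ``'keep'`` ranks |D| with zeros included (Pratt-style,
    so zeros push the other ranks up) but then removes the zero subunits
    from the score set, leaving their sign unrandomized — they contribute
    only a constant.
    """
    if zero_policy not in ("drop", "keep"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    d = data.d
    nonzero = d != 0
    if not nonzero.any():
        raise ValueError("degenerate paired data: all differences are zero")
    if zero_policy == "drop":
        w = midrank(np.abs(d[nonzero]))
    else:  # keep: zeros occupy the lowest ranks, then drop from the score set
        w = midrank(np.abs(d))[nonzero]
    # re-code clusters in case one was emptied entirely
    labels = data.cluster_labels[data.cluster[nonzero]]
    ds = PairedClusteredDataset(labels, d[nonzero])
    arm = (ds.d > 0).astype(np.int8)
    return ScoreSet(ds.cluster, w, arm, np.ones(ds.n_clusters), test="wsr")


_SURVIVAL_WEIGHTS = ("lr", "gw", "pw")


def survival_scores(data: ClusteredDataset, weight: str = "lr") -> ScoreSet:
    """Weighted-logrank observed-minus-expected scores from pooled risk sets.

    For subject (i, j):

        w_ij = sum over pooled distinct event times t_k <= y_ij of
               W(t_k) * [dN_ij(t_k) - d_k / Y(t_k)],

    where Y(t) is the pooled number at risk, d_k the pooled event count at
    t_k, and the scalar weight is W(t) = 1 (``lr``), Y(t)/N (``gw``), or
    the left-continuous pooled Kaplan–Meier estimate S^-(t) (``pw``).
    Tied event times use the Nelson–Aalen increment d_k/Y(t_k). The
    scores sum to zero over all subjects (martingale-residual structure).
    """
    weight = weight.lower()
    if weight not in _SURVIVAL_WEIGHTS:
        raise ValueError(f"weight must be one of {_SURVIVAL_WEIGHTS}, got {weight!r}")
    y = data.y
    if (y < 0).any():
        raise ValueError("survival times must be nonnegative")
    delta = data.events().astype(bool)
    if not delta.any():
        raise ValueError("no events observed: survival scores are undefined")
    N = y.size

    t_event = np.unique(y[delta])                    # pooled distinct event times
    d_k = np.array([(delta & (y == t)).sum() for t in t_event], dtype=float)
    Y_k = np.array([(y >= t).sum() for t in t_event], dtype=float)

    if weight == "lr":
        W_k = np.ones_like(t_event)
    elif weight == "gw":
        W_k = Y_k / N
    else:  # pw: left-continuous pooled Kaplan-Meier at each event time
        km = np.cumprod(1.0 - d_k / Y_k)
        W_k = np.concatenate([[1.0], km[:-1]])

    # cumulative weighted hazard sum_{t_k <= y} W_k d_k / Y_k
    cum = np.concatenate([[0.0], np.cumsum(W_k * d_k / Y_k)])
    idx = np.searchsorted(t_event, y, side="right")
    expected = cum[idx]
    # own event contribution W(y_ij) * dN_ij
    pos = np.searchsorted(t_event, y)
    observed = np.where(delta, W_k[np.minimum(pos, t_event.size - 1)], 0.0)
    w = observed - expected
    return ScoreSet(data.cluster, w, data.arm, np.ones(data.n_clusters),
                    test=weight)


def assemble_scores(scores: ScoreSet, v_rule: str = "unit",
                    center: bool = True) -> ScoreSet:
    """Attach cluster weights and (optionally) center scores within clusters.

    ``v_rule='unit'`` sets v_i = 1; ``'wilcoxon_type'`` sets
    v_i = 1/(n_i + 1). Centering replaces w_ij by w_ij - mean_j(w_ij)
    within each cluster so the permutation mean of S is exactly 0.
    """
    if v_rule == "unit":
        v = np.ones(scores.n_clusters)
    elif v_rule == "wilcoxon_type":
        v = 1.0 / (scores.n_i + 1.0)
    else:
        raise ValueError(f"unknown v_rule {v_rule!r}")
    w = scores.scores
    if center:
        w = w - scores.cluster_means()[scores.cluster]
    return ScoreSet(scores.cluster, w, scores.arm, v, test=scores.test,
                    centered=center, tie_policy=scores.tie_policy)


def build_scores(data, test: str, *, v_rule: str = "unit", center: bool = True,
                 zero_policy: str = "drop") -> ScoreSet:
    """Dispatch: raw scores for ``test`` then assembly (weights, centering)."""
    test = test.lower()
    if test == "ds":
        raw = ds_scores(data)
    elif test == "wsr":
        if not isinstance(data, PairedClusteredDataset):
            raise TypeError("the wsr test requires paired data")
        raw = wsr_scores(data, zero_policy=zero_policy)
    elif test in _SURVIVAL_WEIGHTS:
        raw = survival_scores(data, weight=test)
    else:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    return assemble_scores(raw, v_rule=v_rule, center=center)
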