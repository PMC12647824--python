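"""Double saddlepoint approximation of the within-cluster permutation mid-p.

The permutation law of the treatment labels is represented exactly as the
conditional law of independent Bernoulli(p_i) variables X_ij given the
cluster sums  sum_j X_ij = w_i. With tilt coefficients a_ij = v_i * w_ij
and T = sum_ij a_ij X_ij, the joint cumulant generating function is

    K(t, s) = sum_i sum_j log(1 - p_i + p_i * exp(t a_ij + s_i)),

and the tail probability P(S > s_obs) conditional on the constraints is
approximated by a Lugannani–Rice-type formula built from two saddlepoints:
the numerator saddle (t_hat, s_hat) solving grad K = (s_obs, w_1..w_M),
and the denominator saddle s0_hat solving the same system at t = 0. The
continuous formula

    mid-p ~= 1 - Phi(r) + phi(r) (1/u - 1/r)

directly targets the mid-p-value P(S > s_obs) + 1/2 P(S = s_obs) of the
discrete statistic.

Numerical strategy
------------------
* The nuisance probabilities default to p_i = w_i/n_i, which makes the
  denominator saddle exactly zero.
* The (M+1)-dimensional saddle system is solved by nested profiling:
  for fixed t each s_i(t) solves a monotone one-dimensional equation
  (safeguarded Newton with bisection bracket); the profiled outer
  equation in t is strictly increasing and solved the same way. This is
  mathematically identical to the full multidimensional Newton solve but
  unconditionally stable and O(M) per iteration.
* K'' is never materialized: its arrow structure gives
  det K'' = (prod_i K_ss,ii) * (K_tt - sum_i K_ts,i^2 / K_ss,ii),
  evaluated in log space.
* Clusters with w_i in {0, n_i} or constant scores have no randomness;
  they are dropped from the active system and their fixed contribution is
  subtracted from s_obs.
* Near the permutation mean (|t_hat| < 1e-3) the 1/r - 1/u difference is
  numerically catastrophic; the mid-p is then obtained by symmetric
  evaluation of the same formula at s_obs -+ a small offset and linear
  interpolation, which is smooth and preserves monotonicity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .perm import observed_statistic
from .scores import ScoreSet

__all__ = [
    "CGFModel",
    "SaddlepointSolution",
    "SupportBoundaryError",
    "cgf",
    "solve_numerator_saddle",
    "denominator_saddle",
    "r_u_statistics",
    "dsa_midp",
]

#: |t_hat| below which the direct Lugannani-Rice evaluation is unstable:
#: K(t,s) is a sum of N order-one terms, so the r-bracket (of size
#: ~ sigma^2 t^2 / 2) keeps only ~ 16 + 2 log10(t) digits and 1/r - 1/u
#: turns to noise for |t| much below 1e-4
SMALL_T = 1e-3
#: convergence tolerance (scaled) for the saddle residuals
RESIDUAL_TOL = 1e-8
MAX_OUTER_ITER = 60


class SupportBoundaryError(ValueError):
    """s_obs is at or beyond the boundary of the attainable lattice."""


@dataclass(frozen=True)
class CGFModel:
    """Active-cluster tilting model for the conditional Bernoulli CGF.

    Only *active* clusters — those with 0 < w_i < n_i and non-constant
    tilt coefficients — enter the saddle system; the remaining clusters
    contribute the deterministic offset ``fixed_offset`` to S.
    """

    a: np.ndarray          # flat tilt coefficients over active clusters
    idx: np.ndarray        # active-cluster index per entry of `a`
    n: np.ndarray          # active cluster sizes
    w1: np.ndarray         # active cluster treated counts (constraints)
    p: np.ndarray          # nuisance Bernoulli probabilities
    fixed_offset: float    # deterministic part of S from inactive clusters
    logit_p: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if ((self.p <= 0) | (self.p >= 1)).any():
            raise ValueError("nuisance probabilities must lie strictly in (0,1)")
        object.__setattr__(self, "logit_p", logit(self.p))

    @property
    def n_active(self) -> int:
        return int(self.n.size)

    @classmethod
    def from_scores(cls, scores: ScoreSet, p: np.ndarray | None = None) -> "CGFModel":
        a_all = scores.tilt_coefficients()
        n_all, w_all = scores.n_i, scores.w_i
        a_list, idx_list, n_act, w_act, p_act = [], [], [], [], []
        fixed = 0.0
        k = 0
        for i in range(scores.n_clusters):
            ai = a_all[scores.cluster == i]
            wi, ni = int(w_all[i]), int(n_all[i])
            constant = ai.size == 0 or (np.ptp(ai) == 0.0)
            if wi == ni:
                fixed += float(ai.sum())
            elif wi == 0:
                pass
            elif constant:
                fixed += float(ai[0]) * wi
            else:
                a_list.append(ai)
                idx_list.append(np.full(ai.size, k, dtype=np.intp))
                n_act.append(ni)
                w_act.append(wi)
                p_act.append(wi / ni if p is None else float(np.asarray(p).ravel()[i]))
                k += 1
        if k == 0:
            return cls(np.empty(0), np.empty(0, dtype=np.intp),
                       np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp),
                       np.empty(0), fixed)
        return cls(np.concatenate(a_list), np.concatenate(idx_list),
                   np.asarray(n_act, dtype=np.intp), np.asarray(w_act, dtype=np.intp),
                   np.asarray(p_act, dtype=float), fixed)

    def negated(self) -> "CGFModel":
        """Model of -S (used for lower-tail probabilities)."""
        return CGFModel(-self.a, self.idx, self.n, self.w1, self.p,
                        -self.fixed_offset)

    def support(self) -> tuple[float, float]:
        """Attainable (min, max) of the active part of S."""
        lo = hi = 0.0
        for k in range(self.n_active):
            ak = np.sort(self.a[self.idx == k])
            w = int(self.w1[k])
            lo += ak[:w].sum()
            hi += ak[-w:].sum()
        return float(lo), float(hi)


def cgf(model: CGFModel, t: float, s: np.ndarray):
    """K(t, s) with analytic gradient and Hessian blocks.

    Returns a dict with keys ``K``, ``Kt``, ``Ks`` (vector), ``Ktt``,
    ``Kts`` (vector), ``Kss`` (diagonal vector — cross-cluster second
    derivatives vanish by independence). All terms are computed through
    the log-stable form  log(1-p+p e^eta) = log(1-p) + softplus(eta + logit p)
    and  mu = expit(eta + logit p).
    """
    s = np.asarray(s, dtype=float)
    if not (np.isfinite(t) and np.isfinite(s).all()):
        raise ValueError("non-finite saddle coordinates")
    eta = t * model.a + s[model.idx] + model.logit_p[model.idx]
    mu = expit(eta)
    var = mu * (1.0 - mu)
    A = model.n_active
    log1mp = np.log1p(-model.p)
    K = float(np.sum(model.n * log1mp) + np.sum(np.logaddexp(0.0, eta)))
    Ks = np.bincount(model.idx, weights=mu, minlength=A)
    Kt = float(np.sum(model.a * mu))
    Kss = np.bincount(model.idx, weights=var, minlength=A)
    Kts = np.bincount(model.idx, weights=model.a * var, minlength=A)
    Ktt = float(np.sum(model.a * model.a * var))
    return {"K": K, "Kt": Kt, "Ks": Ks, "Ktt": Ktt, "Kts": Kts, "Kss": Kss}


@dataclass
class SaddlepointSolution:
    t_hat: float
    s_hat: np.ndarray
    s0_hat: np.ndarray
    num: dict               # CGF blocks at (t_hat, s_hat)
    den: dict               # CGF blocks at (0, s0_hat)
    r_tilde: float = math.nan
    u_tilde: float = math.nan
    iterations: int = 0
    residual: float = math.nan
    fallback_used: bool = False


def _solve_s(model: CGFModel, t: float, s_init: np.ndarray | None = None,
             tol: float = 1e-11, max_iter: int = 200) -> np.ndarray:
    """Per-cluster inner saddles s_i(t): solve K_s_i(t, s) = w_i.

    Each equation is strictly increasing in s_i; a vectorized safeguarded
    Newton (bisection bracket maintained per cluster) converges globally.
    """
    A = model.n_active
    if A == 0:
        return np.empty(0)
    amax = np.bincount(model.idx, weights=np.abs(model.a), minlength=A)
    bound = abs(t) * amax + np.abs(model.logit_p) + 60.0
    lo, hi = -bound, bound
    s = np.zeros(A) if s_init is None else s_init.copy()
    s = np.clip(s, lo, hi)
    target = model.w1.astype(float)
    for _ in range(max_iter):
        eta = t * model.a + s[model.idx] + model.logit_p[model.idx]
        mu = expit(eta)
        f = np.bincount(model.idx, weights=mu, minlength=A) - target
        if np.all(np.abs(f) <= tol * np.maximum(model.n, 1)):
            break
        hi = np.where(f > 0, s, hi)
        lo = np.where(f < 0, s, lo)
        fp = np.bincount(model.idx, weights=mu * (1 - mu), minlength=A)
        step = np.where(fp > 0, f / np.maximum(fp, 1e-300), 0.0)
        s_new = s - step
        outside = (s_new <= lo) | (s_new >= hi)
        s = np.where(outside, 0.5 * (lo + hi), s_new)
    return s


def denominator_saddle(model: CGFModel) -> np.ndarray:
    """The t = 0 saddle s0_hat. With p_i = w_i/n_i it is exactly zero;
    for general p_i the per-cluster monotone equations are solved."""
    if model.n_active == 0:
        return np.empty(0)
    if np.max(np.abs(model.p - model.w1 / model.n)) < 1e-13:
        return np.zeros(model.n_active)
    return _solve_s(model, 0.0)


def _profiled_outer(model: CGFModel, t: float, s_init=None):
    s = _solve_s(model, t, s_init)
    blocks = cgf(model, t, s)
    with np.errstate(divide="ignore", invalid="ignore"):
        schur = blocks["Ktt"] - float(np.sum(blocks["Kts"] ** 2 / blocks["Kss"]))
    if not math.isfinite(schur):
        schur = -1.0   # saturated tilt: fall back to bisection steps
    return s, blocks, schur


def solve_numerator_saddle(model: CGFModel, s_obs: float) -> SaddlepointSolution:
    """Solve grad K(t_hat, s_hat) = (s_obs, w_1..w_M) by nested profiling.

    ``s_obs`` here is the *active* part of the observed statistic (the
    deterministic offset already removed) and must lie strictly inside
    the open support interval of the attainable lattice.
    """
    lo_sup, hi_sup = model.support()
    span = max(hi_sup - lo_sup, 1e-12)
    if not (lo_sup + 1e-12 * span < s_obs < hi_sup - 1e-12 * span):
        raise SupportBoundaryError(
            f"s_obs={s_obs} is at or beyond the attainable support "
            f"[{lo_sup}, {hi_sup}]")

    # Gaussian-tilt initial guess: t0 = (s_obs - mean) / var on the a-scale
    A = model.n_active
    mean_a = 0.0
    var_a = 0.0
    for k in range(A):
        ak = model.a[model.idx == k]
        nk, wk = int(model.n[k]), int(model.w1[k])
        mean_a += wk / nk * ak.sum()
        dev = ak - ak.mean()
        var_a += wk * (nk - wk) / (nk * (nk - 1)) * np.sum(dev * dev)
    t = (s_obs - mean_a) / max(var_a, 1e-300)

    # bracket the strictly increasing profiled equation g(t) = Kt - s_obs
    s, blocks, schur = _profiled_outer(model, t)
    g = blocks["Kt"] - s_obs
    step = max(1.0, abs(t))
    t_lo = t_hi = t
    g_lo = g_hi = g
    while g_lo > 0:
        t_lo -= step
        step *= 2
        s, blocks, schur = _profiled_outer(model, t_lo, s)
        g_lo = blocks["Kt"] - s_obs
    step = max(1.0, abs(t))
    while g_hi < 0:
        t_hi += step
        step *= 2
        s, blocks, schur = _profiled_outer(model, t_hi, s)
        g_hi = blocks["Kt"] - s_obs

    tol = RESIDUAL_TOL * max(1.0, abs(s_obs))
    fallback = False
    it = 0
    t = 0.5 * (t_lo + t_hi)
    for it in range(1, MAX_OUTER_ITER + 1):
        s, blocks, schur = _profiled_outer(model, t, s)
        g = blocks["Kt"] - s_obs
        if abs(g) <= tol:
            break
        if g > 0:
            t_hi = t
        else:
            t_lo = t
        if schur > 0:
            t_new = t - g / schur
        else:
            t_new = math.nan
        if not (t_lo < t_new < t_hi):
            t_new = 0.5 * (t_lo + t_hi)   # safeguarded bisection step
            fallback = True
        t = t_new
    den = cgf(model, 0.0, denominator_saddle(model))
    return SaddlepointSolution(t_hat=float(t), s_hat=s,
                               s0_hat=denominator_saddle(model),
                               num=blocks, den=den, iterations=it,
                               residual=float(abs(g)), fallback_used=fallback)


def r_u_statistics(model: CGFModel, sol: SaddlepointSolution,
                   s_obs: float) -> tuple[float, float]:
    """The signed-root statistic r and curvature statistic u.

    r = sgn(t_hat) sqrt(2 [ (K(0,s0) - w.s0) - (K(t,s) - s_obs t - w.s) ])
    u = t_hat sqrt( det K''(t_hat, s_hat) / det K''_ss(0, s0_hat) )

    The bracket in r is analytically nonnegative and clamped at zero to
    guard roundoff. The determinant ratio uses the arrow factorization
    det K'' = (prod_i K_ss,ii) * Schur, in log space — the full
    (M+1)x(M+1) matrix is never formed.
    """
    t, s, s0 = sol.t_hat, sol.s_hat, sol.s0_hat
    w = model.w1.astype(float)
    legendre_den = sol.den["K"] - float(w @ s0)
    legendre_num = sol.num["K"] - s_obs * t - float(w @ s)
    bracket = max(legendre_den - legendre_num, 0.0)
    r = math.copysign(math.sqrt(2.0 * bracket), t)

    schur = sol.num["Ktt"] - float(np.sum(sol.num["Kts"] ** 2 / sol.num["Kss"]))
    if schur <= 0:
        raise ValueError("degenerate curvature (nonpositive Schur complement)")
    log_ratio = (float(np.sum(np.log(sol.num["Kss"])))
                 - float(np.sum(np.log(sol.den["Kss"])))
                 + math.log(schur))
    u = t * math.exp(0.5 * log_ratio)
    return r, u


def _boundary_atom_prob(model: CGFModel, at_max: bool,
                        max_cluster_space: int = 200_000) -> float | None:
    """P(active S equals its extreme) = product over clusters of the
    fraction of size-w subsets attaining the per-cluster extreme sum.
    Returns None when a per-cluster enumeration would be too large."""
    prob = 1.0
    for k in range(model.n_active):
        ak = model.a[model.idx == k]
        w = int(model.w1[k])
        if math.comb(ak.size, w) > max_cluster_space:
            return None
        sums = np.array([sum(c) for c in combinations(ak.tolist(), w)])
        extreme = sums.max() if at_max else sums.min()
        prob *= float(np.mean(np.abs(sums - extreme) <= 1e-9))
    return prob


def _lugannani_rice(r: float, u: float) -> float:
    # classic tail form: 1 - Phi(r) + phi(r) (1/u - 1/r)
    return float(norm.sf(r) + norm.pdf(r) * (1.0 / u - 1.0 / r))


def _dsa_upper(model: CGFModel, s_obs: float, diagnostics: dict | None = None,
               allow_interp: bool = True) -> float:
    """Upper mid-p of the active statistic at active value s_obs."""
    lo_sup, hi_sup = model.support()
    span = max(hi_sup - lo_sup, 1e-12)
    btol = 1e-9 * max(1.0, abs(hi_sup), abs(lo_sup))
    if s_obs >= hi_sup - btol:
        atom = _boundary_atom_prob(model, at_max=True)
        if diagnostics is not None:
            diagnostics["boundary"] = "max"
            diagnostics["boundary_atom_known"] = atom is not None
        return 0.5 * atom if atom is not None else 0.0
    if s_obs <= lo_sup + btol:
        atom = _boundary_atom_prob(model, at_max=False)
        if diagnostics is not None:
            diagnostics["boundary"] = "min"
            diagnostics["boundary_atom_known"] = atom is not None
        return 1.0 - 0.5 * atom if atom is not None else 1.0

    sol = solve_numerator_saddle(model, s_obs)
    if diagnostics is not None:
        diagnostics["iterations"] = sol.iterations
        diagnostics["residual"] = sol.residual
        diagnostics["fallback_used"] = sol.fallback_used
        diagnostics["t_hat"] = sol.t_hat

    if abs(sol.t_hat) < SMALL_T:
        # near the permutation mean 1/r - 1/u cancels catastrophically;
        # interpolate the formula across a window where t_hat is safe.
        sigma2 = (sol.den["Ktt"]
                  - float(np.sum(sol.den["Kts"] ** 2 / sol.den["Kss"])))
        if not allow_interp or sigma2 <= 0:
            return 0.5 - (s_obs - sol.den["Kt"]) / math.sqrt(
                max(sigma2, 1e-300) * 2 * math.pi)
        delta = 10.0 * SMALL_T * sigma2
        delta = min(delta, 0.25 * (hi_sup - s_obs), 0.25 * (s_obs - lo_sup))
        p_lo = _dsa_upper(model, s_obs - delta, allow_interp=False)
        p_hi = _dsa_upper(model, s_obs + delta, allow_interp=False)
        if diagnostics is not None:
            diagnostics["small_t_interpolated"] = True
        return 0.5 * (p_lo + p_hi)

    r, u = r_u_statistics(model, sol, s_obs)
    sol.r_tilde, sol.u_tilde = r, u
    return min(max(_lugannani_rice(r, u), 0.0), 1.0)


def dsa_midp(scores: ScoreSet, side: str = "upper",
             return_diagnostics: bool = False):
    """Double-saddlepoint mid-p-value for a clustered rank statistic.

    The lower side applies the identical machinery to the negated tilt
    coefficients; the two-sided value is min(1, 2 min(upper, lower)).
    """
    model = CGFModel.from_scores(scores)
    if model.n_active == 0:
        raise ValueError(
            "degenerate permutation distribution: no active clusters")
    s_obs = observed_statistic(scores)
    s_active = s_obs - model.fixed_offset
    diag: dict = {}
    upper = _dsa_upper(model, s_active, diag)
    lower = _dsa_upper(model.negated(), -s_active)
    result = {"upper": upper, "lower": lower,
              "two_sided": min(1.0, 2.0 * min(upper, lower))}
    if side in result:
        out = result[side]
    elif side == "two-sided":
        out = result["two_sided"]
    elif side == "all":
        out = result
    else:
        raise ValueError(f"unknown side {side!r}")
    if return_diagnostics:
        return out, diag
    return out
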