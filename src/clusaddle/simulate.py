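"""Synthetic clustered data with controlled intra-cluster correlation.

Survival data follow a shared gamma frailty model: each cluster draws one
frailty u_i from a Gamma with mean 1 and variance theta; conditional on
u_i a subject's hazard is u_i * h0(t) * exp(beta * zeta), and event times
come from inverse-transform sampling, T = H0^{-1}(-log V / (u_i e^{beta
zeta})), with an exponential (H0(t) = lambda t) or Weibull (H0(t) =
lambda t^alpha) cumulative baseline. Administrative censoring applies a
fixed cut-off C: Y = min(T, C), event = I(T <= C).

Paired data follow a hierarchy u_i ~ Gamma(mean 1, var theta);
Z_ij ~ N(u_i, sigma_z^2); Y1 = Z + eps1, Y2 = Z + beta + eps2 with
standard normal errors; the analyzed differences are D = Y2 - Y1. As
written the differences D = beta + eps2 - eps1 are independent of the
cluster effects; an optional ``paired_error_icc`` mixes a shared
cluster-level component into the errors to induce within-cluster
correlation of the differences.

``run_scenario_grid`` sweeps scenario x test x engine cells and reports
empirical rejection rates at a nominal level with binomial Monte Carlo
standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .api import rank_test
from .data import ClusteredDataset, PairedClusteredDataset

__all__ = [
    "SimulationScenario",
    "draw_frailty",
    "simulate_survival",
    "simulate_paired",
    "calibrate_censoring",
    "run_scenario_grid",
]


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of the simulation grid.

    Defaults mirror the study conditions: exponential baseline hazard
    with rate 0.1 (or Weibull with shape 1.5, rate 0.05), balanced
    clusters of size 4 or unbalanced sizes uniform on {2..8}, gamma
    frailty variance theta, null effect beta = 0, no censoring unless a
    censoring time is set.
    """

    M: int = 10
    size_rule: str = "fixed"          # 'fixed' or 'uniform'
    fixed_size: int = 4
    size_range: tuple = (2, 8)        # inclusive, for 'uniform'
    theta: float = 0.5
    baseline: str = "exponential"     # 'exponential' or 'weibull'
    lam: float = 0.1
    alpha_shape: float = 1.5
    beta: float = 0.0
    censoring_time: float | None = None
    sigma_z: float = 1.0
    paired_error_icc: float = 0.0     # 0 = errors independent, as specified
    seed: int | None = None

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.lam <= 0 or self.alpha_shape <= 0:
            raise ValueError("baseline hazard parameters must be positive")
        if self.size_rule not in ("fixed", "uniform"):
            raise ValueError("size_rule must be 'fixed' or 'uniform'")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError("baseline must be 'exponential' or 'weibull'")

    def cluster_sizes(self, rng: np.random.Generator) -> np.ndarray:
        if self.size_rule == "fixed":
            return np.full(self.M, self.fixed_size, dtype=int)
        lo, hi = self.size_range
        return rng.integers(lo, hi + 1, size=self.M)


def draw_frailty(theta: float, rng: np.random.Generator, size=None):
    """Gamma frailty with mean 1 and variance theta (theta = 0 -> exactly 1)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if theta == 0:
        return 1.0 if size is None else np.ones(size)
    return rng.gamma(shape=1.0 / theta, scale=theta, size=size)


def _inverse_cumhaz(scenario: SimulationScenario, x: np.ndarray) -> np.ndarray:
    """Solve H0(T) = x for T."""
    if scenario.baseline == "exponential":
        return x / scenario.lam
    return (x / scenario.lam) ** (1.0 / scenario.alpha_shape)


def simulate_survival(scenario: SimulationScenario,
                      rng: np.random.Generator) -> ClusteredDataset:
    """Shared-frailty survival data for the two-sample tests.

    Within each cluster w_i = floor(n_i / 2) subjects are assigned to
    treatment by a random within-cluster permutation; clusters of size 1
    cannot hold both arms and are redrawn under the 'uniform' size rule.
    """
    sizes = scenario.cluster_sizes(rng)
    sizes = np.maximum(sizes, 2)   # both arms must be represented
    cluster_id = np.repeat(np.arange(scenario.M), sizes)
    N = int(sizes.sum())

    arm = np.zeros(N, dtype=np.int8)
    start = 0
    for n_i in sizes:
        w_i = int(n_i) // 2
        pick = rng.permutation(int(n_i))[:w_i]
        arm[start + pick] = 1
        start += int(n_i)

    u = np.repeat(draw_frailty(scenario.theta, rng, size=scenario.M), sizes)
    V = rng.uniform(size=N)
    rate_mult = u * np.exp(scenario.beta * arm)
    T = _inverse_cumhaz(scenario, -np.log(V) / rate_mult)

    if scenario.censoring_time is None:
        return ClusteredDataset(cluster_id, T, arm,
                                np.ones(N, dtype=np.int8))
    C = float(scenario.censoring_time)
    y = np.minimum(T, C)
    event = (T <= C).astype(np.int8)
    return ClusteredDataset(cluster_id, y, arm, event)


def simulate_paired(scenario: SimulationScenario,
                    rng: np.random.Generator) -> PairedClusteredDataset:
    """Clustered paired differences for the signed-rank test."""
    sizes = scenario.cluster_sizes(rng)
    cluster_id = np.repeat(np.arange(scenario.M), sizes)
    N = int(sizes.sum())
    u = np.repeat(draw_frailty(scenario.theta, rng, size=scenario.M), sizes)
    z = rng.normal(loc=u, scale=scenario.sigma_z)
    rho = scenario.paired_error_icc
    if rho > 0:
        # optional cluster-shared error components; drawn separately for
        # the two visits so the shared part survives in D = Y2 - Y1 and
        # the differences correlate within clusters
        shared1 = np.repeat(rng.normal(size=scenario.M), sizes)
        shared2 = np.repeat(rng.normal(size=scenario.M), sizes)
        eps1 = math.sqrt(rho) * shared1 + math.sqrt(1 - rho) * rng.normal(size=N)
        eps2 = math.sqrt(rho) * shared2 + math.sqrt(1 - rho) * rng.normal(size=N)
    else:
        eps1 = rng.normal(size=N)
        eps2 = rng.normal(size=N)
    y1 = z + eps1
    y2 = z + scenario.beta + eps2
    return PairedClusteredDataset.from_pairs(cluster_id, y1, y2)


def calibrate_censoring(scenario: SimulationScenario, target: float,
                        rng: np.random.Generator, n_subjects: int = 100_000,
                        tol: float = 0.005) -> float:
    """Administrative censoring time C giving the target censoring
    fraction, by bisection on a large Monte Carlo draw of event times."""
    if not 0 < target < 1:
        raise ValueError("target censoring fraction must be in (0, 1)")
    per = max(scenario.fixed_size, 2)
    m = n_subjects // per
    big = replace(scenario, M=m, censoring_time=None, size_rule="fixed",
                  fixed_size=per)
    T = simulate_survival(big, rng).y
    # censoring fraction at C is P(T > C); pick C at the target quantile
    return float(np.quantile(T, 1.0 - target))


def run_scenario_grid(scenarios, tests=("ds",), engines=("dsa",),
                      reps: int = 1000, alpha: float = 0.05,
                      B: int = 10_000, seed: int | None = 0,
                      progress: bool = False) -> pd.DataFrame:
    """Empirical rejection rates over a scenario grid.

    For each scenario a fresh child generator simulates ``reps`` null (or
    alternative) datasets; every test x engine combination is evaluated on
    the same datasets. Returns a long-format table with one row per
    scenario x test x engine, including binomial MC standard errors and
    the child seed used.
    """
    master = np.random.default_rng(seed)
    rows = []
    for s_idx, scenario in enumerate(scenarios):
        child_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(child_seed)
        rejections = {(t, e): 0 for t in tests for e in engines}
        for _ in range(reps):
            paired = any(t == "wsr" for t in tests)
            surv_tests = [t for t in tests if t != "wsr"]
            data_s = simulate_survival(scenario, rng) if surv_tests else None
            data_p = simulate_paired(scenario, rng) if paired else None
            for t in tests:
                data = data_p if t == "wsr" else data_s
                res = rank_test(data, t, engines, B=B,
                                seed=int(rng.integers(2**31 - 1)))
                for e in engines:
                    if res.midp[e]["two_sided"] < alpha:
                        rejections[(t, e)] += 1
        for t in tests:
            for e in engines:
                rate = rejections[(t, e)] / reps
                rows.append({
                    "scenario": s_idx, "M": scenario.M,
                    "size_rule": scenario.size_rule,
                    "theta": scenario.theta, "baseline": scenario.baseline,
                    "beta": scenario.beta, "test": t, "engine": e,
                    "reps": reps, "alpha": alpha,
                    "rejection_rate": rate,
                    "mc_se": math.sqrt(max(rate * (1 - rate), 1e-12) / reps),
                    "seed": child_seed,
                })
        if progress:
            print(f"scenario {s_idx + 1}/{len(scenarios)} done")
    return pd.DataFrame(rows)
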