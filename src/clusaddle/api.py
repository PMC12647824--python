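"""High-level one-call interface: build scores, run the requested engines."""

from __future__ import annotations

import numpy as np

from .perm import (EQ_TOL, TestResult, an_midp, exact_midp, mcp_midp,
                   observed_statistic, permutation_moments,
                   permutation_space_size)
from .saddlepoint import dsa_midp
from .scores import build_scores

__all__ = ["rank_test", "ENGINES"]

ENGINES = ("an", "dsa", "mcp", "exact")


def rank_test(data, test: str = "ds", engines=("dsa",), *,
              v_rule: str = "unit", center: bool = True,
              zero_policy: str = "drop", B: int = 100_000,
              seed: int | None = None, max_space: int = 2_000_000) -> TestResult:
    """Run a clustered rank test with one or more p-value engines.

    Parameters
    ----------
    data : ClusteredDataset or PairedClusteredDataset
    test : one of 'ds', 'wsr', 'lr', 'gw', 'pw'
    engines : iterable of 'an', 'dsa', 'mcp', 'exact'
    B : Monte Carlo permutation count for the 'mcp' engine
    seed : seed for the 'mcp' engine's generator

    Returns a :class:`~clusaddle.perm.TestResult` whose ``midp`` maps each
    engine to its upper / lower / two-sided mid-p-values.
    """
    if isinstance(engines, str):
        engines = (engines,)
    unknown = [e for e in engines if e not in ENGINES]
    if unknown:
        raise ValueError(f"unknown engine(s) {unknown}; expected {ENGINES}")
    scores = build_scores(data, test, v_rule=v_rule, center=center,
                          zero_policy=zero_policy)
    mean, var = permutation_moments(scores)
    result = TestResult(test=test, s_obs=observed_statistic(scores),
                        perm_mean=mean, perm_var=var)
    result.diagnostics["v_rule"] = v_rule
    result.diagnostics["centered"] = center
    result.diagnostics["space"] = permutation_space_size(scores)
    for engine in engines:
        if engine == "an":
            upper = an_midp(scores, "upper")
            result.midp["an"] = {"upper": upper, "lower": 1.0 - upper,
                                 "two_sided": min(1.0, 2 * min(upper, 1 - upper))}
        elif engine == "dsa":
            vals, diag = dsa_midp(scores, side="all", return_diagnostics=True)
            result.midp["dsa"] = vals
            result.diagnostics["dsa"] = diag
        elif engine == "mcp":
            rng = np.random.default_rng(seed)
            upper, s_b = mcp_midp(scores, B, rng, "upper", return_draws=True)
            eq = np.abs(s_b - result.s_obs) <= EQ_TOL
            lower = float((np.sum(s_b < result.s_obs - EQ_TOL)
                           + 0.5 * eq.sum()) / B)
            result.midp["mcp"] = {"upper": upper, "lower": lower,
                                  "two_sided": min(1.0, 2 * min(upper, lower))}
            result.diagnostics["mcp"] = {"B": int(B), "seed": seed}
        elif engine == "exact":
            upper = exact_midp(scores, "upper", max_space=max_space)
            lower = exact_midp(scores, "lower", max_space=max_space)
            result.midp["exact"] = {"upper": upper, "lower": lower,
                                    "two_sided": min(1.0, 2 * min(upper, lower))}
    return result
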