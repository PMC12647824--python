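"""Confidence intervals for the treatment effect by test inversion.

A (1 - alpha) interval for the effect parameter beta is the set of
hypothesized values beta_0 that the chosen rank test does not reject at
level alpha after the data are adjusted to conform to H0: beta = beta_0:

* survival data (accelerated-failure-time ``log_time_shift``): subtract
  beta_0 from the log event times of the treated arm, i.e. multiply
  treated observed times by exp(-beta_0); censoring times shift along
  with event times, so event indicators are unchanged;
* paired data (``location_shift``): subtract beta_0 from every paired
  difference.

Scores are recomputed from the adjusted data for every beta_0 — the rank
structure changes with the shift. Interval endpoints are located by
bisection on the two-sided p-value; the point estimate is the beta_0 at
which the standardized statistic crosses zero (a Hodges–Lehmann-style
inversion midpoint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import ClusteredDataset, PairedClusteredDataset
from .perm import an_midp, exact_midp, mcp_midp, observed_statistic, \
    permutation_moments
from .saddlepoint import dsa_midp
from .scores import build_scores

__all__ = ["CIResult", "shift_adjust", "invert_test", "point_estimate"]


@dataclass
class CIResult:
    estimate: float
    lower: float
    upper: float
    level: float
    test: str
    engine: str
    effect_model: str
    #: (beta_0, two-sided p) pairs evaluated during inversion
    trace: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate, "lower": self.lower,
            "upper": self.upper, "level": self.level, "test": self.test,
            "engine": self.engine, "effect_model": self.effect_model,
            "trace": [[float(b), float(p)] for b, p in self.trace],
            "diagnostics": self.diagnostics,
        }


def shift_adjust(data, beta0: float, effect_model: str):
    """Adjust data to conform to the null hypothesis beta = beta_0."""
    if effect_model == "log_time_shift":
        if not isinstance(data, ClusteredDataset):
            raise TypeError("log_time_shift applies to survival data")
        if beta0 == 0.0:
            return data
        treated = data.arm == 1
        if (data.y[treated] <= 0).any():
            raise ValueError("log_time_shift requires strictly positive times")
        y = data.y.copy()
        y[treated] = y[treated] * math.exp(-beta0)
        return data.with_y(y)
    if effect_model == "location_shift":
        if not isinstance(data, PairedClusteredDataset):
            raise TypeError("location_shift applies to paired data")
        if beta0 == 0.0:
            return data
        return data.with_d(data.d - beta0)
    raise ValueError(f"unknown effect_model {effect_model!r}")


def _default_effect_model(data) -> str:
    return ("location_shift" if isinstance(data, PairedClusteredDataset)
            else "log_time_shift")


def _pvalue_fn(test, engine, v_rule, center, B, seed, state=None):
    """Two-sided p as a function of beta_0-adjusted data. For the MCP
    engine the same seed is reused at every beta_0 (common random
    numbers), keeping the p-curve effectively monotone. A ``state`` dict,
    when given, records whether the last evaluation was degenerate (the
    adjusted data carried no permutation randomness at all)."""

    if engine not in ("an", "dsa", "exact", "mcp"):
        raise ValueError(f"unknown engine {engine!r}")

    def p_of(data):
        # a beta0 so extreme that the adjusted data carry no permutation
        # randomness (every cluster one-sided / constant) provides no
        # evidence against that beta0: two-sided mid-p = 1
        if state is not None:
            state["degenerate"] = False
        try:
            scores = build_scores(data, test, v_rule=v_rule, center=center)
        except ValueError:
            if state is not None:
                state["degenerate"] = True
            return 1.0
        if permutation_moments(scores)[1] <= 0:
            if state is not None:
                state["degenerate"] = True
            return 1.0
        if engine == "dsa":
            return dsa_midp(scores, side="two_sided")
        if engine == "an":
            return an_midp(scores, side="two-sided")
        if engine == "exact":
            u = exact_midp(scores, "upper")
            return min(1.0, 2 * min(u, 1 - u))
        rng = np.random.default_rng(seed)
        return mcp_midp(scores, B, rng, "two-sided")

    return p_of


def _standardized(data, test, v_rule, center) -> float:
    """(S - mean)/sd of the beta0-adjusted data; signed sentinel values at
    degenerate configurations (all arms on one side carry maximal
    evidence; an exactly-null degenerate set carries none)."""
    try:
        scores = build_scores(data, test, v_rule=v_rule, center=center)
    except ValueError:
        return 0.0   # e.g. all paired differences exactly zero: exact null
    mean, var = permutation_moments(scores)
    if var <= 0:
        drift = float(np.mean(2.0 * scores.arm.astype(float) - 1.0))
        return 1e6 * drift if abs(drift) > 0.999 else 0.0
    return (observed_statistic(scores) - mean) / math.sqrt(var)


def _initial_scale(data) -> float:
    if isinstance(data, PairedClusteredDataset):
        s = float(np.std(data.d))
        return max(s, 1e-3)
    return 1.0   # log-time shifts live on a unit-ish scale


def point_estimate(data, test: str, effect_model: str | None = None, *,
                   v_rule: str = "unit", center: bool = True,
                   tol: float = 1e-6, max_expand: int = 60) -> float:
    """beta at which the standardized statistic crosses zero.

    The statistic is a decreasing step function of beta_0 (treated
    outcomes are shifted down as beta_0 grows); bisection on its sign
    locates the crossing to resolution ``tol``.
    """
    effect_model = effect_model or _default_effect_model(data)

    def z(b):
        return _standardized(shift_adjust(data, b, effect_model), test,
                             v_rule, center)

    # symmetric geometric expansion: the statistic is monotone in beta0
    # (decreasing for location shifts, increasing for log-time shifts),
    # so a sign change is eventually bracketed either way.
    scale = _initial_scale(data)
    h = scale
    for _ in range(max_expand):
        z_lo, z_hi = z(-h), z(h)
        if z_lo == 0.0 and z_hi == 0.0:
            return 0.0
        if z_lo * z_hi <= 0:
            break
        h *= 2
    else:
        raise ValueError("could not bracket the point estimate")
    lo, hi = -h, h
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        zm = z(mid)
        if zm == 0.0:
            # exact crossing or locally flat: shrink symmetrically
            lo, hi = 0.5 * (lo + mid), 0.5 * (hi + mid)
            continue
        if (zm > 0) == (z_hi > z_lo):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _scan_for_crossing(p_of_beta, probes, alpha, direction, points=48):
    """Fine sweep over the outermost expansion gaps, looking for the
    rejection dip that the coarse walk may have stepped over (the p-curve
    dips below alpha just before the data degenerate, then rebounds).
    Returns an (inner, outer) bracket with p(inner) >= alpha > p(outer),
    or None if no crossing is found."""
    if len(probes) < 2:
        return None
    a = probes[max(0, len(probes) - 6)]
    b = probes[-1]
    grid = np.linspace(a, b, points)
    prev = a
    for x in grid[1:]:
        if p_of_beta(float(x)) < alpha:
            return float(prev), float(x)
        prev = x
    return None


def _find_endpoint(p_of_beta, trace, beta_hat, alpha, direction, scale,
                   max_expand=40, p_tol=1e-3, b_tol=1e-4,
                   allow_unbounded=False, degenerate_state=None):
    """Locate the beta where the two-sided p crosses alpha on one side of
    the estimate. ``direction`` is +1 (upper endpoint) or -1 (lower).

    With very sparse information the permutation lattice is coarse and
    the p-value can stay above alpha no matter how far the data are
    shifted (far enough out every cluster becomes one-sided and the
    conditional test carries no evidence at all): the endpoint is then
    genuinely unbounded. That raises "unbracketable endpoint" unless
    ``allow_unbounded`` is set, in which case +-inf is returned.

    The outward walk uses gently growing steps because the p-curve is
    not monotone all the way out — it dips through the rejection region
    and rebounds to 1 once the data degenerate — so a coarse doubling
    could leap straight over the crossing.
    """
    inner = beta_hat
    p_inner = p_of_beta(inner)
    step = scale
    cap = 600.0 * max(scale, 1.0)   # keeps exp(-beta0) finite
    outer = inner + direction * step
    p_outer = p_of_beta(outer)
    probes = [inner, outer]
    expansions = 0
    while p_outer >= alpha:
        at_cap = abs(outer - beta_hat) >= cap
        degenerate = degenerate_state.get("degenerate", False) \
            if degenerate_state is not None else False
        if expansions >= max_expand or at_cap or degenerate:
            bracket = _scan_for_crossing(p_of_beta, probes, alpha, direction)
            if bracket is not None:
                inner, outer = bracket
                p_inner = p_of_beta(inner)
                p_outer = p_of_beta(outer)
                break
            if allow_unbounded:
                return direction * math.inf
            raise ValueError(
                "unbracketable endpoint: p-value never fell below alpha "
                f"in direction {direction:+d} (flat p; see trace)")
        inner, p_inner = outer, p_outer
        step *= 1.6
        outer = beta_hat + direction * min(abs(outer - beta_hat) + step, cap)
        p_outer = p_of_beta(outer)
        probes.append(outer)
        expansions += 1
    trace.append((inner, p_inner))
    trace.append((outer, p_outer))
    # bisection: p >= alpha at inner, < alpha at outer
    while abs(outer - inner) > b_tol:
        mid = 0.5 * (inner + outer)
        p_mid = p_of_beta(mid)
        trace.append((mid, p_mid))
        if abs(p_mid - alpha) <= p_tol:
            return mid
        if p_mid >= alpha:
            inner = mid
        else:
            outer = mid
    return 0.5 * (inner + outer)


def invert_test(data, test: str = "ds", engine: str = "dsa",
                level: float = 0.95, effect_model: str | None = None, *,
                v_rule: str = "unit", center: bool = True,
                B: int = 10_000, seed: int | None = 0,
                allow_unbounded: bool = False) -> CIResult:
    """Test-inversion confidence interval for the treatment effect.

    Endpoints satisfy two_sided_p(beta) = 1 - level to within 1e-3 in p
    or 1e-4 in beta. The search bracket grows geometrically away from
    the point estimate until the p-value falls below alpha.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    effect_model = effect_model or _default_effect_model(data)
    alpha = 1.0 - level
    state: dict = {}
    p_raw = _pvalue_fn(test, engine, v_rule, center, B, seed, state=state)

    trace: list = []

    def p_of_beta(b):
        p = p_raw(shift_adjust(data, b, effect_model))
        return p

    beta_hat = point_estimate(data, test, effect_model, v_rule=v_rule,
                              center=center)
    scale = _initial_scale(data)
    upper = _find_endpoint(p_of_beta, trace, beta_hat, alpha, +1, scale,
                           allow_unbounded=allow_unbounded,
                           degenerate_state=state)
    lower = _find_endpoint(p_of_beta, trace, beta_hat, alpha, -1, scale,
                           allow_unbounded=allow_unbounded,
                           degenerate_state=state)
    trace.sort(key=lambda bp: bp[0])
    return CIResult(estimate=beta_hat, lower=lower, upper=upper, level=level,
                    test=test, engine=engine, effect_model=effect_model,
                    trace=trace,
                    diagnostics={"alpha": alpha, "B": B, "seed": seed,
                                 "n_evaluations": len(trace)})
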