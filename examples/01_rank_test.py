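"""Run a clustered logrank test with all four p-value engines.

Simulates a small multi-center-style survival study (10 clusters, shared
gamma frailty, no treatment effect), then compares the asymptotic-normal,
double-saddlepoint, Monte Carlo and exact-enumeration mid-p-values for
the clustered logrank test.
"""

import numpy as np

from clusaddle import SimulationScenario, rank_test, simulate_survival

# 8 balanced clusters of 4 keep the permutation space at 6^8 ~ 1.7e6,
# small enough for the exact-enumeration engine to run too
scenario = SimulationScenario(M=8, theta=2.0, baseline="exponential",
                              lam=0.1, beta=0.0)
data = simulate_survival(scenario, np.random.default_rng(42))
print(f"{data.n_clusters} clusters, {data.n_subjects} subjects, "
      f"{int(data.events().sum())} events")

result = rank_test(data, test="lr", engines=("an", "dsa", "mcp", "exact"),
                   B=100_000, seed=0)
print(f"S_obs = {result.s_obs:.4f}, permutation sd = "
      f"{result.perm_var ** 0.5:.4f}, space = {result.diagnostics['space']}")
for engine in ("an", "dsa", "mcp", "exact"):
    p = result.midp[engine]
    print(f"{engine:>5}: upper mid-p = {p['upper']:.4f}   "
          f"two-sided = {p['two_sided']:.4f}")

print("\nThe saddlepoint (dsa) value should sit within a few thousandths of")
print("the exact enumeration and the B=1e5 Monte Carlo benchmark, at a tiny")
print("fraction of their cost; data were simulated under the null, so none")
print("of the tests should typically reject.")
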