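"""Type I error of the saddlepoint test across a small scenario grid.

Reruns a miniature version of the null calibration study: clustered
survival data from a shared gamma frailty model at two correlation
levels, tested with the Datta-Satten statistic under the asymptotic-
normal and saddlepoint engines.
"""

from clusaddle import SimulationScenario, run_scenario_grid

grid = [SimulationScenario(M=10, theta=0.5, baseline="exponential", lam=0.1),
        SimulationScenario(M=10, theta=2.0, baseline="exponential", lam=0.1)]

table = run_scenario_grid(grid, tests=("ds",), engines=("an", "dsa"),
                          reps=500, alpha=0.05, seed=3)
print(table[["M", "theta", "test", "engine", "rejection_rate",
             "mc_se"]].to_string(index=False))

print("\nEach row is the fraction of 500 null datasets rejected at the 5%")
print("level (with its binomial standard error). Both engines standardize")
print("by the exact within-cluster permutation moments, so both should sit")
print("near 0.05; the saddlepoint additionally corrects the tail shape.")
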