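# clusaddle

Accurate p-values and confidence intervals for rank-based two-sample and
paired tests on **clustered data**, computed against the within-cluster
permutation distribution with a **double saddlepoint approximation**.

## The problem

In multi-center trials, toxicology litter studies and recurrent-event
data, observations come in clusters: outcomes within a cluster (patients
in a clinic, littermates, repeated admissions of one patient) are
correlated, while clusters are independent. Rank tests — the
Datta–Satten cluster-adjusted rank-sum, the clustered Wilcoxon
signed-rank, and weighted logrank statistics for right-censored survival
times — remain valid here *if* they are referred to the right null
distribution: the **within-cluster permutation distribution**, in which
treatment labels are reshuffled only inside each cluster with the
per-cluster group sizes held fixed.

That distribution is exact but combinatorial: its support has
∏ᵢ C(nᵢ, wᵢ) points, which is astronomically large for routine data, and
Monte Carlo permutation with B = 10⁶ draws takes minutes per p-value.
`clusaddle` replaces both with an analytic approximation that is
accurate to a few thousandths and runs in milliseconds.

## The method

Every supported test is a linear rank statistic

    S = Σᵢ vᵢ Σⱼ w_ij ζ_ij ,

with fixed scores `w_ij` computed once from the observed outcomes
(mid-ranks for ties, risk-set logic for censoring), cluster weights `vᵢ`,
and random treatment labels `ζ_ij`. The permutation law of the labels is
represented exactly as the law of independent Bernoulli(pᵢ) variables
X_ij conditioned on the cluster sums Σⱼ X_ij = wᵢ. The joint cumulant
generating function

    K(t, s) = Σᵢ Σⱼ log(1 − pᵢ + pᵢ e^{t vᵢ w_ij + sᵢ})

then yields a double (conditional) saddlepoint approximation of the
**mid-p-value** P(S > s_obs) + ½P(S = s_obs): solve ∇K(t̂, ŝ) =
(s_obs, w₁…w_M) for the numerator saddle, the t = 0 system for the
denominator saddle (exactly 0 when pᵢ = wᵢ/nᵢ), and plug the signed-root
statistic r̃ and curvature statistic ũ into the Lugannani–Rice-type tail
formula

    mid-p ≈ 1 − Φ(r̃) + φ(r̃)(1/ũ − 1/r̃).

Alongside the saddlepoint engine (`dsa`) the package ships the
asymptotic-normal engine (`an`, exact permutation moments), a Monte Carlo
permutation benchmark (`mcp`), and exact enumeration (`exact`) for small
spaces — plus test-inversion confidence intervals, a point estimate, and
shared gamma-frailty / clustered-paired data simulators.

## Worked example

`examples/01_rank_test.py` simulates a null 8-cluster survival study from
a shared gamma frailty model (θ = 2, exponential baseline λ = 0.1) and
compares all four engines on the clustered logrank test:

```
8 clusters, 32 subjects, 32 events
S_obs = 0.2244, permutation sd = 1.1398, space = 1679616
   an: upper mid-p = 0.4220   two-sided = 0.8439
  dsa: upper mid-p = 0.4259   two-sided = 0.8518
  mcp: upper mid-p = 0.4257   two-sided = 0.8514
exact: upper mid-p = 0.4272   two-sided = 0.8544
```

The saddlepoint value sits within 0.0013 of the full 1.7-million-point
enumeration while touching the CGF only a handful of times. The other
examples invert the clustered signed-rank test into a confidence interval
for a paired shift (`02_confidence_interval.py`) and rerun a miniature
Type I error grid (`03_type_one_error_grid.py`).

The same analyses are available from the shell:

```
clusrank-saddle test --input data.csv --test lr --engine dsa,mcp --B 100000 --seed 7
clusrank-saddle ci   --input data.csv --test ds --engine dsa --level 0.95
clusrank-saddle simulate --grid grid.yaml --reps 2000 --out rates.tsv
```

Survival input is a CSV/TSV with columns `cluster,y,event,arm`; paired
input has `cluster,subunit,d` (or `y1`/`y2`).

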