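# Methods

## Model and reference distribution

The data are M independent clusters; cluster i holds nᵢ subunits with
outcome y_ij and binary treatment label ζ_ij, of which wᵢ = Σⱼ ζ_ij are
treated. All tests are linear rank statistics S = Σᵢ vᵢ Σⱼ w_ij ζ_ij and
all inference refers to the **within-cluster permutation distribution**:
labels are exchangeable inside a cluster conditional on (wᵢ, nᵢ), and
clusters permute independently, so the null support is the product of the
per-cluster C(nᵢ, wᵢ) assignments. This conditional exchangeability is
what a blocked randomization scheme guarantees in a randomized trial; in
observational data it is an assumption.

Scores are computed **once** from the observed outcomes and never
recomputed under permutation:

* **Datta–Satten (ds)** — w_ij = 1 + ½ Σ_{k≠i} (F_k(y_ij) + F_k(y_ij⁻))
  with F_k the empirical CDF of cluster k and F_k(·⁻) its left limit;
  scores lie in [1, M]. With censored data the construction is applied
  to the observed times, ignoring event indicators (the EDF-based
  definition has no censoring adjustment; this is deliberate and
  flagged here).
* **Clustered Wilcoxon signed-rank (wsr)** — pooled mid-ranks of |D_ij|
  with ζ_ij = I(D_ij > 0). Zero differences are dropped before ranking
  by default; a Pratt-style `keep` policy ranks through the zeros and
  then removes them, so they influence other ranks but contribute no
  randomness.
* **Weighted logrank (lr / gw / pw)** — per-subject observed-minus-
  expected sums over pooled risk sets, w_ij = Σ_{t_k ≤ y_ij} W(t_k)
  [dN_ij(t_k) − d_k/Y(t_k)], with scalar weight W(t) = 1 (logrank),
  Y(t)/N (Gehan–Wilcoxon) or the left-continuous pooled Kaplan–Meier
  estimate (Prentice–Wilcoxon). Tied event times use the Nelson–Aalen
  increment d_k/Y(t_k). The classical two-sample integrand weights carry
  an additional Y₁Y₂/(Y₁+Y₂) factor; that factor is variance
  normalization and is supplied here by the permutation distribution
  itself, so the per-subject scores use the scalar weight only. The
  construction is validated against a brute-force evaluation of the
  defining sum and against exact enumeration, not against a closed form.
  Scores sum to zero over subjects (martingale-residual structure);
  an event occurring exactly at the censoring time counts as an event.

Cluster weights vᵢ default to 1 (`unit`); vᵢ = 1/(nᵢ+1)
(`wilcoxon_type`) is available. Scores are centered within clusters by
default so the permutation mean of S is exactly 0; the variance

    Var(S) = Σᵢ vᵢ² · wᵢ(nᵢ−wᵢ)/(nᵢ(nᵢ−1)) · Σⱼ (w_ij − w̄ᵢ)²

is the exact variance under within-cluster permutation (verified against
enumeration). Both defaults exist because the simulation literature for
these tests rarely states its choices; both are switchable.

## The double saddlepoint engine

The permutation law of the labels equals the law of independent
Bernoulli(pᵢ) variables conditioned on the cluster sums; pᵢ is a free
nuisance constant and is fixed at wᵢ/nᵢ, which makes the t = 0
(denominator) saddle exactly **0** and leaves the conditional answer
unchanged (a tilt in sᵢ absorbs any change of pᵢ; the r̃/ũ statistics are
invariant). The joint CGF is

    K(t, s) = Σᵢⱼ log(1 − pᵢ + pᵢ e^{t a_ij + sᵢ}),   a_ij = vᵢ w_ij,

evaluated in log-stable form (softplus / expit; no overflow for
|η| ≤ 700). Clusters with wᵢ ∈ {0, nᵢ} or constant scores carry no
randomness: they are removed from the active system and their fixed
contribution is subtracted from s_obs.

**Solver.** Rather than an (M+1)-dimensional Newton iteration, the
saddle system is solved by nested profiling: for fixed t each ŝᵢ(t)
solves a strictly increasing one-dimensional equation (safeguarded
Newton with a maintained bisection bracket, vectorized over clusters);
the profiled outer equation in t is strictly increasing with derivative
equal to the Schur complement K_tt − Σᵢ K_ts,ᵢ²/K_ss,ᵢᵢ > 0, and is
solved the same way. This is mathematically the same solution,
unconditionally convergent, and O(N) per iteration. Residual tolerance
1e-8·max(1, |s_obs|), at most 60 outer iterations, bisection fallback
recorded in the diagnostics.

**Tail formula.** With the Legendre difference
Δ = (K(0,ŝ₀) − wᵀŝ₀) − (K(t̂,ŝ) − s_obs t̂ − wᵀŝ) (clamped at ≥ 0
against roundoff), r̃ = sgn(t̂)√(2Δ) and
ũ = t̂ √(det K″(t̂,ŝ) / det K″_ss(0,ŝ₀)); the determinant ratio uses the
arrow structure det K″ = (Πᵢ K_ss,ᵢᵢ)·Schur in log space, so no matrix is
ever formed. The discrete mid-p is approximated by the continuous
Lugannani–Rice form

    mid-p ≈ 1 − Φ(r̃) + φ(r̃)(1/ũ − 1/r̃).

The ordering of the correction term matters: the variant with
(1/r̃ − 1/ũ) is grossly wrong (checked against exact enumeration: a
4-subject cluster instance gives 0.113 versus a true mid-p of 0.250,
while the form above gives 0.244).

**Near the mean.** K is a sum of N order-one terms, so Δ ≈ σ²t̂²/2
retains only about 16 + 2·log₁₀|t̂| significant digits; below |t̂| ≈ 1e-4
the 1/ũ − 1/r̃ difference is numerical noise. For |t̂| < 1e-3 the engine
therefore evaluates the same formula at s_obs ∓ δ (δ = 0.01·σ², clamped
inside the support) and interpolates linearly — smooth, monotone, and
second-order accurate since the mid-p is locally near-linear. (An
analytic third-cumulant limit would serve the same purpose; the
interpolation was chosen because it reuses the validated main path.)

**Boundaries and degeneracy.** s_obs at the lattice maximum returns
½·P(S = max), with the atom computed from per-cluster subset
enumerations when feasible and 0 (flagged) otherwise; the minimum is
symmetric. An instance with no active clusters raises a degeneracy
error. The lower tail is computed by negating the tilt coefficients;
two-sided p-values use min(1, 2·min(upper, lower)) throughout — the
sidedness convention is isolated in one place because published
rejection-rate tables rarely state theirs.

**Accuracy.** Against exact enumeration, |DSA − exact| mid-p is
max ≈ 0.005 / median ≈ 0.001 for M ∈ {8..10}, nᵢ ∈ {4..6}, degrading on
very coarse lattices (max ≈ 0.08 when M, nᵢ ∈ {2..5}, where the support
can have only a handful of atoms — no smooth tail approximation can do
better there, and the exact engine is cheap precisely there). The
continuous formula is also not reliable in the outermost few percent of
the attainable range, where the monotonicity test is therefore
restricted to the interior.

## Other engines

* `an`: Φ applied to the statistic standardized by its exact permutation
  moments. Note this comparator is *calibrated by construction* at the
  scale of its variance; its error is purely non-normality of shape.
* `mcp`: the B-draw estimator B⁻¹(Σ I(S_b > S_obs) + ½ Σ I(S_b = S_obs)),
  with statistic equality decided at 1e-9 absolute (mid-ranked scores
  are small-denominator rationals, so genuinely distinct atoms differ by
  far more). Sampling is vectorized (per-cluster uniform subsets via
  arg-partition of uniforms).
* `exact`: full product enumeration, refused above 2·10⁶ assignments;
  clusters in input order, subsets lexicographic (order-invariance is
  tested).

## Confidence intervals

A (1−α) interval for the effect β is the set of β₀ not rejected after
adjusting the data to H₀: β = β₀. Survival data use the accelerated-
failure-time adjustment y → y·e^{−β₀} for treated subjects (censoring
times shift with event times, so event indicators are unchanged — the
choice that preserves the null construction); paired data use d → d−β₀.
Scores are recomputed at every β₀. The estimate is the β₀ where the
standardized statistic crosses zero (a Hodges–Lehmann-style inversion
midpoint); because the conditional standardization changes discretely as
signs/ranks flip, the crossing is locally jumpy and the bisection
returns one of the nearby crossings — the estimator is unbiased in
simulation (mean error < 0.01 at M = 30) but noisier per dataset than
its unconditional cousin.

Endpoints are found by bisection on two-sided p(β₀) − α (tolerance 1e-3
in p or 1e-4 in β), with an outward walk of gently growing steps
(×1.6) from the estimate. The walk matters: far enough out every
cluster becomes one-sided, the conditional test degenerates and p
rebounds to 1, so the p-curve dips through the rejection region and
rises again. If the coarse walk overshoots, a 48-point sweep of the
outermost gaps recovers the crossing; if p genuinely never falls below α
(very sparse data), the endpoint is unbounded — reported as an
"unbracketable endpoint" error, or as ±inf when `allow_unbounded=True`.
MCP-engine inversion reuses one seed across all β₀ (common random
numbers) so its p-curve is effectively monotone.

Note the estimand: with the y·e^{−β₀} adjustment, inversion on data from
a proportional-hazards generator targets the true **log time-shift**,
which is −β for an exponential baseline and −β/α for a Weibull baseline
with shape α — not the log hazard ratio β itself. Coverage is therefore
evaluated at that implied shift. The semiparametric alternative (a
frailty-model Wald interval) is deliberately not reimplemented here:
it is off-the-shelf estimation available from established survival
fitters, and the package's AN comparator is the AN-engine inversion CI.

## Synthetic data generators

The survival generator is a shared gamma frailty model: uᵢ ~ Gamma(mean
1, variance θ) once per cluster (θ = 0 degenerates to 1 exactly);
conditional hazard uᵢ·h₀(t)·e^{βζ}; T = H₀⁻¹(−log V / (uᵢ e^{βζ})) by
inverse transform with H₀(t) = λt (exponential, λ = 0.1) or λt^α
(Weibull, α = 1.5, λ = 0.05 — the λt^α parameterization is a package
choice isolated in one function; it affects the time scale only, not
null rank behavior). Administrative censoring uses a fixed cut-off C:
Y = min(T, C), Δ = I(T ≤ C); `calibrate_censoring` returns the empirical
(1−target)-quantile of a large simulated draw of event times, the exact
fixed point of tuning C to a target censoring fraction. Treatment is
allocated within clusters as wᵢ = ⌊nᵢ/2⌋ via random permutation
(allocation is not otherwise pinned down for such studies; balance
guarantees non-degenerate clusters), and cluster sizes are fixed at 4 or
uniform on {2..8}. Null scenarios are uncensored unless a censoring
time is configured; the effect scenarios use β = log 1.5 with 20%
censoring, and the paired effect scenarios β = 0.5.

The paired generator draws uᵢ ~ Gamma(1, θ), Z_ij ~ N(uᵢ, σ_Z²) with
σ_Z = 1, Y₁ = Z + ε₁, Y₂ = Z + β + ε₂, ε ~ N(0,1) i.i.d., and analyzes
D = Y₂ − Y₁. As written, D = β + ε₂ − ε₁ is **independent of the
cluster effects** — the hierarchy cancels in the difference — so θ does
not induce correlation among the differences. The generator implements
this hierarchy exactly as stated; an optional `paired_error_icc` mode
draws separate cluster-shared components for ε₁ and ε₂ so the
differences do correlate within clusters (corr = icc), for studying how
cluster correlation would affect the tests.

What passing tests on these generators shows: correct null calibration
and coverage under gamma frailty with administrative censoring and
balanced within-cluster randomization. What they do not show: behavior
under informative censoring, covariate-dependent frailties, cluster-level
treatment assignment, or observational confounding — all outside the
model class.

## Problem sizes used in the validation suite

The automated checks run at sizes chosen to give informative Monte Carlo
error at interactive cost: 200 instances for saddlepoint-vs-enumeration
agreement; 2,000 null replicates for the Type I error cell (binomial SE
≈ 0.005); 200 replicates × B = 10⁵ for saddlepoint-vs-Monte-Carlo
agreement; 500 replicates for CI coverage (SE ≈ 0.010) and for paired
effect recovery; 10,000 replicates in the acceptance script's Type I
error computation. Seeds are fixed in tests and derived from `--seed`
in the acceptance script.

## Known limitations

* First-order saddlepoint only; no third-order (ρ₃/ρ₄) refinement, so
  very coarse lattices (≲ 10² atoms) show absolute mid-p errors up to a
  few hundredths. Use the exact engine there — it is cheap exactly when
  the saddlepoint is weakest.
* Two treatment arms only; no stratification, interval censoring or
  covariate adjustment.
* The conditional (fixed-wᵢ) inversion CI can be unbounded on very
  sparse data; this is a property of the conditional test, not a solver
  failure.
* The Datta–Satten scores use the plain EDF on observed times under
  censoring (no censoring-adjusted EDF).
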