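# Methods

This note documents the models, the numerical choices, and the synthetic
data generator, in enough detail to audit or extend any stage.

## Data model and trait transforms

Trees are rooted with branch lengths in Ma; the crown age T is the maximum
root-to-tip distance, and ultrametricity is checked as
max_i |depth_i − T| / T ≤ tol (default tol = 1e-3, configurable).  The
verdict is invariant to tip order; OU fits refuse trees beyond the
tolerance rather than silently proceeding.

Traits are analysed on transformed scales: natural log for nectar volume
(μL) and amino-acid concentration (mM); logit for sugar concentration
(% w/w), sucrose proportion (%) and the amino-acid fractions.
Percentages are divided by 100 first, so logit offsets apply on the
proportion scale: an offset of 0.001 is added when zeros occur in the
percentage traits, and the amino-acid fractions always use logit(x + 0.01).
Back-transformation inverts these exactly (round trip to 1e-10), which is
how optima and confidence intervals are reported in natural units.
Replicate rows per species in a trait table (repeated nectar samples) are
averaged on the raw scale before transformation; species missing a trait
are dropped from that trait's analyses only (the spur regressions
typically run on a 48-species subset).

## Regime reconstruction (Mk-ER)

Pollination syndrome (five classes: bird, butterfly, bee, fly,
bee-and-butterfly — this fixed order is also the tie-break and
treatment-coding order) evolves as a continuous-time Markov chain with a
single rate q between every ordered state pair.  The equal-rates
transition probabilities have the closed form
P_ii(t) = 1/k + (k−1)/k·e^{−kqt}, P_ij(t) = 1/k − 1/k·e^{−kqt}.
The likelihood is computed by pruning with per-node rescaling; the root
carries a uniform prior.  q̂ maximizes the likelihood by bounded search on
log q over [1e-8/T, 1e3/T] (coarse grid then Brent refinement);
monomorphic tip states return q = 0 with a warning flag instead of
failing.  Ancestral states are *marginal* posteriors (down messages from
pruning, up messages propagated preorder).  Every node is assigned its
argmax state (ties broken toward the lowest state index, logged) and every
branch inherits the state of its tipward endpoint; terminal branches use
the observed tip state.  The tipward-endpoint rule is one convention among
several — nothing in the likelihood forces it — but it yields exactly one
regime per branch, which is the form the Hansen machinery needs.

The ML rate was cross-checked against an independent implementation
during development and agrees exactly; note that some implementations
report the Mk log-likelihood without the uniform root prior factor
(a constant offset of ln k that does not affect the rate estimate).

## The six trait-evolution models

All models are Gaussian at the tips, so each log-likelihood is a
multivariate-normal density with a model-specific mean and covariance
(C is the shared root-to-MRCA path-length matrix):

| model   | mean            | covariance                          | k |
|---------|-----------------|-------------------------------------|---|
| WN      | μ               | s²·I                                | 2 |
| BM.s    | z₀              | σ²·C                                | 2 |
| Lambda  | z₀              | σ²·C with off-diagonals × λ, λ∈[0,1]| 3 |
| BM.rate | z₀              | Σ_r σ²_r·C_r                        | 1+R |
| OU.s    | θ               | σ²/(2α)·e^{−αd}(1−e^{−2αs})         | 3 |
| OU.poll | W(α)·θ          | as OU.s                             | 2+R |

C_r accumulates only the shared path length spent in regime r
(Σ_r C_r = C).  For OU on an ultrametric tree, d is the patristic tip–tip
distance and s the shared depth.  The Hansen weight W_{ir} integrates
α·e^{−α(T−t)} over the segments lineage i spends in regime r, plus a root
weight e^{−αT} credited to the root's regime, so rows sum to one; there is
no separately estimated root optimum, and a single α and σ² are shared
across regimes.  Parameter counts k are as tabulated (means counted;
R = number of regimes present in the painting).

Fitting profiles everything linear analytically: for a given α (or λ, or
rate vector), the optima/means solve by generalized least squares and σ²
by its ML closed form, leaving a 1-D search over log α on
[1e-9/T, 1e3/T] (or λ on [0,1]) — a deterministic coarse grid (13 and 11
points respectively) followed by bounded Brent refinement around the best
three grid points.  BM.rate has no common scale to profile, so the R log
rates are optimized by L-BFGS-B from three deterministic starts (the BM.s
rate ×1, ×0.1, ×10).  Convergence tolerances: 1e-10 on the search
variable; likelihood evaluations failing Cholesky return +∞ to the
optimizer.  Exact fits (zero residual) are floored at rss = 1e-300 to
keep profiled likelihoods finite; constant traits are rejected as
degenerate.

Model support: AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) and Akaike weights
w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2).  Per-model fit failures are recorded
without aborting the comparison.  OU fits also report the phylogenetic
half-life t½ = ln 2/α.

**Identifiability caveat.** When the generating t½ is far below the
shortest branch lengths, tip values are effectively at stationarity and
the likelihood is flat in α above a threshold: α̂ then sits at the search
bound and only a lower bound on α (upper bound on t½) is meaningful.  The
optima and their uncertainties remain well identified in this regime.

### Uncertainty of the optima

Standard errors come from the inverse numerical Hessian (central
differences, relative step 1e-4) of the negative log-likelihood at the ML
point in the (θ₁..θ_R, log α, log σ²) parameterization; 95 % CIs are
θ̂ ± 1.96·se on the transformed scale and are back-transformed afterwards,
giving asymmetric natural-scale intervals.  If the Hessian is singular or
yields non-positive variances, a seeded parametric bootstrap (199
replicates, refitting the same model to data simulated from the ML fit)
replaces it and the output is flagged.

## PGLS with jointly estimated λ

Residual covariance σ²·C_λ; λ and the coefficients are estimated
simultaneously (for each λ the GLS solutions are closed-form; the profiled
likelihood is maximized over λ∈[0,1]).  On an ultrametric tree λ = 0
reproduces OLS exactly and λ = 1 the classic BM PGLS.  Categorical
syndrome enters by treatment coding with bird as reference, in the fixed
order butterfly, bee, fly, bee-and-butterfly.  Coefficient tests are
two-sided t on n − p df using the unbiased residual variance; no
multiple-testing correction is applied.  AICc uses the ML likelihood and
counts λ as a parameter when it is estimated (k = p + 1 + 1); this
convention matters when comparing regressions with and without predictors
and is stated here because reasonable software differs on it.  Exact fits
report a capped |t| of 1e6.  Profile-likelihood CIs for λ in the
trait-signal context are computed on the unconstrained surface, so upper
bounds may exceed 1.

## Multivariate nectar syndrome

The clustering variables are the transformed volume, sugar concentration,
sucrose proportion and amino-acid concentration plus the first three axes
of a PCA of the logit(x+0.01) amino-acid fractions, each z-scored
(population sd) before Euclidean distances.  PCA is the SVD of the
centered (and, with scale=True, unit-variance) matrix; axis signs follow a
deterministic convention (largest-magnitude loading positive) and
variable–axis correlations are reported alongside loadings.  UPGMA uses
average linkage with node heights at half the merge distance, so the
dendrogram is exactly ultrametric and cophenetic tip-to-tip distances
equal the merge distances; ties resolve in leftmost-pair order.

The syndrome distance is 0 within a class, 0.5 between bee or butterfly
and the mixed bee-and-butterfly class, and 1 otherwise.  The Mantel test
correlates lower-triangle entries, permutes one matrix's labels jointly
(rows and columns), and is one-sided for positive association with
p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm); the default n_perm is 9999 and
all permutations are seeded.

**λ signal of syndrome on the dendrogram.**  The syndrome is dummy-coded
into state-membership indicators; a single λ scales the dendrogram's
off-diagonal shared-path covariance, per-indicator means and variances are
profiled by GLS, and λ̂ maximizes the summed profile likelihood over
[0, 1].  λ = 0 is exactly the star-phylogeny (white noise) model, tested
by LRT with a 1-df χ² reference.  A discrete Mk likelihood with a free
transition rate was considered and rejected: as the rate grows, any tree
fits independent tip states equally well, so λ is unidentified under the
null (shuffled labels gave median λ̂ ≈ 0.9 under the Mk reading versus
0.0 under the Gaussian-indicator reading, which also cleanly detects
constructed two-cluster signal with λ̂ = 1).  This stage treats the
dendrogram as a similarity structure, not an evolutionary tree, so the
Gaussian analogy is appropriate.

## Synthetic data generator

The generator emulates the study design, not any particular dataset:

- **Tree**: Yule tree conditioned on n = 57 tips and crown age 22.0 Ma
  (an alternative 23.7 Ma total height is selectable).  Besides the crown
  split, node depths are iid with CDF (e^{λt} − 1)/(e^{λT} − 1) from the
  root — the exact age-conditioned pure-birth law — with topology from
  uniform pair joins backward in time; the birth rate defaults to
  ln(n/2)/T so the expected tip count at T equals n.  This construction
  was chosen over rescaling unconditioned waiting times because it hits
  the crown age exactly *and* has a closed-form branching-time law the
  test suite verifies by Kolmogorov–Smirnov.
- **Syndromes**: ER Mk jumps simulated along branches (default rate
  0.02/Ma, root state bee), re-drawn with a shifted stream until all five
  classes occur at the tips; the full within-branch jump history is kept
  for trait simulation and collapsed to one regime per branch when
  exported as a painting.
- **Traits**: simulated under any of the six models by preorder recursion
  (OU segment-wise across regime changes:
  x′ ~ N(θ_r + (x−θ_r)e^{−αt}, σ²(1−e^{−2αt})/(2α))).  The bundle's
  defaults use the reported magnitudes: volume/sugar/sucrose under
  OU.poll with (α, σ²) = (14.9, 5.42)/(15.0, 29.4)/(14.9, 58.1) on their
  transformed scales and reported syndrome optima (e.g. 37.1 μL for
  bird-pollinated volume); amino-acid concentration under OU.s with
  θ = 3.40 mM, α = 0.45, σ² = 0.26.  Natural-scale values are clipped
  into the observed ranges (volume 0.06–72.16 μL; sugar 0.73–76.9 %;
  sucrose 25.2–99.8 %; amino acids 0.20–69.70 mM) because those σ²
  magnitudes occasionally exceed the observed extremes.
- **Amino-acid fractions**: logistic-normal with three latent factors
  (fixed loading pattern; factor scales 1.1/0.9/0.5, residual sd 0.75)
  and no phylogenetic structure, so a few ordination axes carry most of
  the compositional variance, as in real nectar amino-acid profiles.
- **Spur lengths**: total spur under OU.poll (bird longest), spur a
  0.65 fraction with small lognormal noise; nine species lack spur data,
  giving the 48-species regression subset.

What the generator does *not* emulate: measurement error and replicate
structure, correlated evolution between traits (each trait draws an
independent realization on the shared regime history — associations among
traits arise only through the syndromes), non-Yule tree shape, extinction,
and within-species variation.  Passing tests therefore demonstrate
correctness of the estimators under the assumed models at the study's
sample sizes, not robustness to those violations.

## Problem sizes and determinism

Every stochastic routine is a pure function of its inputs and a seed;
pipelines derive all stage seeds from the config seed, and two runs with
the same seed produce byte-identical reports (timings aside).  The test
suite's simulation studies use the sizes stated with each property
(e.g. 200 replicates at 57 tips for optimum recovery, 100 for
model-selection power, 500 for p-value calibration, 1000 small trees for
the branching-time law); the acceptance script runs one full 57-species
analysis with 9999 Mantel permutations.
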