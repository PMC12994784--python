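# Methods

## The models

All four models regress a quantitative trait `y` (length n) on a matrix of
SNP minor-allele dosages `X` (n × p, entries 0/1/2), and differ in the prior
on the marker effects β and in whether a kinship-correlated polygenic term
is present.

**Spike-and-slab (SSVS).** A continuous two-component mixture on each
effect:

    y_i = x_i'β + ε_i,              ε_i ~ N(0, σ_ε²)
    β_j | γ_j, σ² ~ N(0, [γ_j v1 + (1 − γ_j) v0] σ²)
    γ_j ~ Bernoulli(π),  σ² ~ IG(ν/2, νλ/2),  σ_ε² ~ IG(a, b)

Defaults v0 = 0.00025, v1 = 1, ν = 10, λ = 125, a = b = 0.001, π = 1/2.
π is fixed (no hyperprior), matching the Bernoulli(1/2) statement of the
hierarchy; it is configurable. Both mixture components scale with σ², so
the spike is "small" only relative to the slab; the practical consequences
are discussed under *Known limitations*.

**Bayesian LASSO.** β_j ~ Laplace(0, λ) with rate λ, i.e. density
(λ/2)·exp(−λ|β_j|), sampled through the normal–exponential scale mixture
(β_j | τ_j² ~ N(0, τ_j²), τ_j² ~ Exp(λ²/2)). The Gamma(a_λ, b_λ) hyperprior
is placed on λ² — the parameterization with a conjugate Gamma full
conditional — with b_λ read as a rate; a literal scale of 10⁻⁶ would pin
λ ≈ 0 and disable shrinkage, contradicting λ's role as the regularization
parameter. Defaults a_λ = 0.55, b_λ = 10⁻⁶, a_σ = b_σ = 0.5. Unlike the
Park–Casella formulation, the Laplace prior here is not conditioned on σ².

**Bayesian LMM.** β_j ~ N(0, τ²) with fixed τ² (default 1), plus a
polygenic effect u ~ N(0, G σ_u²) with G the kinship matrix and Z = I (one
random effect per individual). σ² and σ_u² carry IG(0.001, 0.001)
hyperpriors. The BLMM is implemented and tested but excluded from the
default cross-validated comparison.

**BSLMM.** Point-mass-plus-slab effects over a polygenic background:

    y_i = μ + x_i'β + u_i + ε_i
    β_j ~ π N(0, σ_a²) + (1 − π) δ₀
    u ~ N(0, σ_b² K),   K = XX'/n
    μ ~ N(0, σ_μ²),  σ_ε⁻² ~ Gamma(α_ε, γ_ε)
    σ_a² ~ IG(α_a, γ_a),  σ_b² ~ IG(α_b, γ_b)
    log π ~ Uniform(log(1/p), 0)

Defaults α_a = 10, γ_a = 0.01, α_b = 10, γ_b = 0.01, α_ε = γ_ε = 0.001;
σ_μ² is the sample variance of y at fit time. The kinship denominator
defaults to n (the printed form of the hierarchy); the /p convention of
the wider BSLMM literature is available by configuration.

## Samplers

All four models use component-wise Gibbs sampling. Single-site β updates
maintain a running residual vector; the update order is a fresh random
permutation each iteration, drawn from the chain's own RNG. Chains are
independent given their seeds (spawned from the master seed and the chain
index), so runs are exactly reproducible and chains could be executed
concurrently without changing results.

Model-specific choices:

- *Spike-and-slab*: β_j from its Gaussian full conditional given the
  current γ_j; then all γ_j jointly from Bernoulli draws whose odds
  multiply π/(1−π) by the slab/spike density ratio at the current β_j;
  σ² pools Σ β_j²/v_j over both mixture states.
- *BLASSO*: latent 1/τ_j² from inverse-Gaussian full conditionals
  (Michael–Schucany–Haas sampler), with |β_j| floored at 10⁻¹⁰ to guard
  the mean parameter; λ² from Gamma(a_λ + p, b_λ + Σ τ_j²/2).
- *BLMM/BSLMM polygenic term*: u is drawn in the eigenbasis of K, computed
  once per fit; eigenvalues below 10⁻¹⁰ are truncated to zero and their
  coordinates pinned at zero (the prior is degenerate there).
- *BSLMM β updates are marginalized*: the slab is integrated analytically
  against the residual likelihood, giving point-mass-vs-slab odds; if
  included, β_j is drawn from its Gaussian full conditional, otherwise set
  exactly to zero. This mixes markedly better than updating (β_j, γ_j)
  conditionally on each other.
- *BSLMM π update*: random-walk Metropolis on log π under the uniform
  prior, proposal sd 0.3, multiplicatively adapted toward a ~0.44
  acceptance rate during burn-in only (so the retained chain is a valid
  Markov chain). When every effect is excluded, σ_a² is refreshed from
  its prior that iteration (counted in the fit metadata).
- Variance draws are floored at 10⁻¹² for positivity.

Default settings mirror the diagnostics protocol (3 chains × 8,000
iterations, 3,000 burn-in); `McmcSettings.final_run()` gives the long
production run (25,000 iterations, 5,000 burn-in, 20,000 retained).

Intercepts: spike-and-slab, BLASSO and BLMM have no μ term, so y is
centered before fitting and the removed mean restored at prediction time;
BSLMM samples μ explicitly. Genotype columns are centered, never scaled,
before fitting, and the kinship matrix is built from the centered matrix.

## Oracles used in tests

- Exact enumeration: for p ≤ 3 with fixed variance components, posterior
  inclusion probabilities are computed by summing conjugate Gaussian
  marginal likelihoods over all 2^p indicator configurations. The MCMC
  PIPs must agree within ±0.02 (continuous spike) / ±0.03 (point mass).
- Conjugate limits: v0 = v1 (spike-and-slab), forced full inclusion with
  no polygenic term (BSLMM), and σ_u² → 0 (BLMM) all collapse to a
  ridge-type Gaussian posterior computed in closed form; posterior means
  must agree within 3 Monte Carlo standard errors (ESS-adjusted).
- Prior-predictive identity: ancestral draws from the BLASSO scale
  mixture must pass a Kolmogorov–Smirnov test against the Laplace law
  (10⁵ draws, α = 0.01).

## Prediction

For each retained draw ℓ the predictive response at new genotypes x* is
simulated as y*(ℓ) = μ(ℓ) + x*'β(ℓ) + u*(ℓ) + ε(ℓ) with
ε(ℓ) ~ N(0, σ_ε²(ℓ)) — the full posterior predictive, noise included.
The point prediction is the Monte Carlo mean over draws and the interval
is formed from empirical quantiles; the default level is 0.90 (5th–95th
percentiles), configurable.

For models with a polygenic term, the test individuals' u* is drawn from
its Gaussian conditional given the training draws: mean K₂₁K₁₁⁻u(ℓ) and
Schur-complement covariance, with K built from the stacked (train + test)
centered dosages and K₁₁ inverted by pseudoinverse with a small jitter
(marker-derived kinships are rank-deficient). A β-only mode is available
for comparison. Noise and polygenic draws use independent RNG substreams
so toggling the polygenic term does not perturb the noise stream.

## Preprocessing

Traits are tested for normality (Shapiro–Wilk by default, computed on a
fixed-seed subsample above n = 5,000 where the statistic loses
calibration; Anderson–Darling by option). Non-normal traits are mapped by
ordered quantile normalization: Φ⁻¹((r_i − 0.5)/n) with averaged ranks
for ties (the rankit offset c = 0.5). The fitted map stores the unique
training values with their normal scores; new values are transformed by
piecewise-linear interpolation, extrapolating linearly from the two edge
knots. In cross-validation the map is always fitted on the training fold
and applied to the held-out fold, and all metrics are computed on the
transformed (modeling) scale — predictions are not back-transformed.

## Cross-validation and metrics

`run_cv` implements 5-fold cross-validation (each fold an 80/20 split):
balanced random partition, per-fold preprocessing as above, every
requested model fitted and evaluated on the held-out fold. Metrics: RMSE,
MAE, empirical coverage of the predictive interval (endpoints inclusive;
not defined for the frequentist models), and model size S. S uses
exact-zero counting for the LASSO, PIP > 0.5 for the indicator models,
and a 90% equal-tailed credible interval excluding zero for the BLASSO
(which never produces exact zeros). Reports carry per-fold values and
mean/min/max aggregates per model. All fold and model seeds derive from
one master seed, so two runs with the same configuration are
byte-identical.

Baselines: OLS is the minimum-norm least-squares solution (pseudoinverse)
so it remains defined at p ≫ n, where it interpolates the training data;
ridge is solved in closed form through one SVD per training set across a
log-spaced 50-point penalty grid; the LASSO uses coordinate descent on
internally standardized predictors with coefficients reported on the
dosage scale. Ridge and LASSO penalties are chosen by inner 5-fold
cross-validation on the training fold only.

## Diagnostics

R̂ is the rank-normalized split potential scale reduction factor and ESS
the autocorrelation-based bulk effective sample size (both via arviz); a
classic split-R̂ is available by flag. Chains with zero internal variance
everywhere return an infinity sentinel (R̂) or NaN (ESS) with a warning
rather than failing. Reported ESS is capped at 10× the retained draw
count, since strongly antithetic chains can exceed the nominal count.
Summaries report avg/min/max over the β coefficients, the quantities of
interest for variable selection.

## The synthetic-data generator

The generator emulates a crop GBS panel and is the union of the fitted
models' generative assumptions, so each model is well-specified under
some configuration:

- *Markers*: per-marker ancestral allele frequencies uniform on
  `maf_range` (default 0.05–0.5); subpopulation frequencies are
  Balding–Nichols Beta perturbations with divergence F
  (`fst_like_divergence`, default 0.05 over 3 balanced subpopulations);
  dosages arise from two haplotypes, each thresholding a latent Gaussian
  that shares a per-block factor with loading √ρ (default ρ = 0.6 over
  blocks of 50 markers), giving Hardy–Weinberg proportions within
  subpopulations and within-block LD. Defaults n = 2,266, p = 12,486
  emulate the scale of the motivating rice panel.
- *Trait*: y = Xβ + u + ε with `n_causal` Gaussian-drawn sparse effects,
  a polygenic term with covariance proportional to the realized kinship,
  and Gaussian noise; components are rescaled so the realized genetic
  variance fraction matches `heritability_target` (default 0.5), split
  between sparse and polygenic layers by `polygenic_fraction`
  (default 0.3). The trait has unit variance up to sampling error.
- *Skewness*: optionally a monotone map (exponential of the standardized
  trait, or a gamma quantile transform) produces a non-normal trait for
  exercising the normalization path; the stored truth stays on the
  pre-skew scale.

What the generator does **not** emulate: genotype missingness and calling
error, linkage that decays with physical distance (blocks are
exchangeable), dominance/epistasis, and trait-specific environmental
structure. Passing tests therefore demonstrate statistical correctness of
the machinery under the assumed architectures, not performance claims
about any real panel.

Experiment designs used by the acceptance checks (chosen once, as the
package's own reading of the study conditions):

- *Recovery*: n = 400, p = 1,000, 10 causal SNPs carrying the full
  h² = 0.5 (`polygenic_fraction = 0`), 5 seeds, single chains of 3,000
  iterations with 1,000 burn-in.
- *Coverage*: n = 500 (300 train / 200 test), p = 200, same architecture,
  3 seeds, 90% intervals.
- The cross-validation smoke panel is n = 150, p = 80 at short chain
  lengths; these sizes keep the default test run fast while leaving every
  code path exercised at realistic shapes.

## Known limitations

- Under the default spike-and-slab hyperparameters (ν = 10, λ = 125), the
  σ² posterior sits far above a unit-variance trait's scale when p is
  moderate, so the "spike" variance v0σ² is not negligible: null markers
  retain a posterior inclusion floor around 0.05 with occasional
  excursions near 0.5, and at n = 400 the model recovers slightly fewer
  causal markers in top-10 rankings than the point-mass BSLMM. This is a
  property of the continuous-mixture prior at these settings, not of the
  sampler (which matches exact enumeration on small problems).
- Gaussian-drawn causal effects make some simulated "causal" markers
  carry essentially zero variance; perfect top-k recovery is not
  attainable by any method under this design.
- The BLASSO's model-size rule (credible-interval exclusion of zero) is
  sensitive to the chosen level; 90% is the default.
- OLS at p ≫ n is reported for completeness but interpolates the
  training data; its out-of-sample error is dominated by variance.
- Single-process execution; chains run sequentially.
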