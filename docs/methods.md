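# Methods

`floaterqg` implements the statistical chain used to study alternative
male mating tactics — territory holding vs floating — in a small, closed,
individually monitored bird population with a multi-generation pedigree.
This note records the models, the conventions behind every numerical
choice, and what the synthetic data can and cannot establish.

## Pedigree relatedness and inbreeding

The additive (numerator) relationship matrix **A** is built by the
recursive tabular method over a parents-before-offspring ordering:

    A[j, i] = (A[sire(j), i] + A[dam(j), i]) / 2
    A[j, j] = 1 + A[sire(j), dam(j)] / 2

Founders are assumed unrelated and non-inbred, so `f_i = A_ii − 1` is 0
for them by construction.  A missing parent is treated as a unique,
unrelated, non-inbred phantom founder — the standard convention, and the
one consistent with an "unrelated founders" baseline.  Because a single
missing parent silently forces `f = 0`, inbreeding analyses are
restricted to individuals whose sire, dam and all four grandparents are
known (`four_grandparent_filter`); this mirrors how pedigrees with a
late-starting paternity assignment are handled in practice and guards
against depth-driven downward bias in *f*.

An `exact=True` mode computes **A** in rational arithmetic
(`fractions.Fraction`); the test suite uses it to demonstrate exact
agreement with two independently coded oracles (recursive coancestry and
Wright's path counting) on random pedigrees.

## Synthetic data

The generator emulates the study conditions rather than any particular
dataset: a closed population grown from 21 founders over 17 breeding
seasons, socially monogamous pairs with a 60% extra-pair siring rate, a
male surplus, complete fledgling observation, and genetic paternity
assignment beginning only in season 6 (dams recorded throughout).  With
the default demography (adult survival 0.68, density-regulated
recruitment around a ceiling of roughly 120–150 birds) a run yields
roughly 700–1000 male-season records on 240–340 males, about a third of
them floater-seasons — the scale of the motivating field data.

Phenotypes are generated from the same latent models the package fits:

* status: `logit P(territorial) = β₀ + β_age·age_s + β_age²·age²_s +
  β_f·f_s + β_tarsus·tarsus_s + a_i + pe_i + yr_t`, with breeding values
  `a ~ MVN(0, σ²_A A)` drawn through a Cholesky factor of the pedigree's
  **A**, permanent-environment and year effects i.i.d. Normal, and the
  Bernoulli draw through the logistic link (the latent residual is the
  standard logistic, variance π²/3).  Defaults: β₀ = 1.1, β_age = 2.3,
  β_age² = −2.2, β_f = −0.35, β_tarsus = 0.45 on the standardized logit
  scale; σ²_A = 0, σ²_PE = 0.6, σ²_year = 0.05.  The year variance is
  deliberately small; published analyses of this system find it near
  zero.
* annual reproductive success: `log E[ARS] = α₀ + 1.15·territorial +
  1.30·age_s − 0.88·age²_s + u_i + v_t` with Poisson counts; α₀ is
  calibrated to −0.8 so the overall mean ARS is ≈ 2 fledglings per
  male-season, matching the observed scale.  The extra-pair component is
  `EPARS = ARS` for floaters and binomial thinning with probability 0.6
  for territorials.

Predictors are simulated on the standardized (sample-sd) scale precisely
because the fitted models standardize predictors; generative
coefficients and estimates therefore live on the same scale.  Tarsus is
a non-heritable Normal(20, 1) trait — no size distribution is published,
and size heritability is out of scope.  Mortality is age-independent
(capped at age 10); senescence in survival is not modelled because none
of the estimators under test depend on it.

Two scenario presets fix study conditions for the recovery tests:
`behaviour_recovery_config` (≈360 complete-case records, the size of the
behaviour analysis) and `animal_model_config` (≈800–960 records, full
paternity, no f/tarsus effects so the variance-component truth is exactly
the model being fitted, with σ²_A solved from a requested latent h²).

All randomness descends from a single integer seed; equal seeds give
byte-identical outputs across processes.

## GLMMs and multimodel inference

Binomial-logit and Poisson-log mixed models with crossed random
intercepts (year, individual) are fitted by maximum likelihood with the
random effects integrated out by a Laplace approximation.  For fixed
variance components, fixed effects and random intercepts are maximized
jointly by penalized IRLS (canonical links, step-halving, relative
tolerance 1e-10); the profiled Laplace log-likelihood

    ℓ(θ) = ℓ_y(η̂) − û'D⁻¹û/2 − log|I + Z'WZ·D|/2

is maximized over the random-effect standard deviations by bounded
L-BFGS-B with numerical gradients.  At a zero variance the fit collapses
exactly to the ordinary GLM (verified against `statsmodels` to 1e-6),
which also anchors the parameter count: `k` = fixed coefficients +
number of free variance parameters, so the intercept+age+age² behaviour
model with two random terms has k = 5 as a published model table of this
kind would report.  On shared fits the fixed effects agree with `lme4::
glmer` to ≈0.1 (both are Laplace approximations with slightly different
profiling; the difference is within the approximation error and far
below a standard error).

Model selection follows the AICc confidence-set recipe: every
marginality-respecting submodel (quadratic age never without linear age;
interactions never without both mains) is fitted on the complete-case
intersection of rows so AICc values are comparable; the confidence set
is ΔAICc strictly below 2; Akaike weights are renormalized over the set.
Coefficients are averaged conditionally ("natural" averaging over the
models containing the term — the default of the multimodel-inference
literature this workflow follows), with full averaging (zeros
substituted) behind a flag.  Confidence intervals use the weighted
unconditional standard error, `Σ w√(se² + (β−β̄)²)`, with Normal
quantiles; relative importance is the summed weight of models containing
the term.  Predictors are standardized to mean 0, sample variance 1;
the quadratic age term is the square of standardized age, standardized
again, and interaction columns are products of standardized mains.

## The animal model

Season-level mating status is analysed as a latent-scale binary trait:

    l = Xβ + Z a + Z pe + Z yr,    status = 1[l + e > 0],  e ~ logistic

with `a ~ N(0, σ²_A A)`, `pe ~ N(0, σ²_PE I)` over individuals and
`yr ~ N(0, σ²_yr I)` over seasons — i.e. exactly a Bernoulli-logit GLMM.
The logistic latent residual is what makes the residual variance a fixed
constant (π²/3 ≈ 3.290) rather than a free parameter, so the latent
phenotypic variance is

    V_P = ΣV_components + π²/3,

and repeatability `R = V_ind/V_P` (model 2a: individual + year) and
heritability `h² = V_A/V_P` (model 2b: additive genetic + permanent
environment + year) are computed **per iteration** before summarizing —
the posterior mean of a ratio is not the ratio of posterior means, and a
regression test pins this down on a deliberately skewed posterior.  A
`include_residual` flag adds a further unit of latent variance to V_P
for comparability with threshold-model conventions that carry a fixed
unit probe residual; it changes only the reported ratios, not the fit.

Sampling is exact Gibbs via Pólya-Gamma data augmentation (`ω_i ~
PG(1, η_i)` renders every location update conditionally Gaussian and
every variance update conditionally inverse-gamma).  Two details matter
for mixing:

* the additive-genetic and permanent-environment effects share identical
  incidence columns, so they are drawn as one joint Gaussian block; a
  Schur complement against the diagonal pe-precision reduces the joint
  draw to a single q-dimensional Cholesky, the same cost as a
  single-site update but without the near-perfect negative coupling of
  the confounded split;
* each sweep ends with a Metropolis scale move per component that
  rescales `(u, σ²)` jointly along the weakly identified ridge (the
  Normal prior exponent is invariant under `u → cu, σ² → c²σ²`, so the
  acceptance ratio is just the Bernoulli likelihood times the
  inverse-gamma prior ratio).  Without this move the conjugate scan
  random-walks in σ² with a relative step of order √(2/q) per iteration.

Even so, lag-1 autocorrelation of the stored genetic and PE variance
draws remains around 0.6–0.8 at the desk-scale default chain (10 000
iterations, burn-in 500, thin 5 — roughly 100× shorter than a
publication-scale run), while the year component mixes to < 0.1.  Longer
chains reproduce the same posteriors (checked at 20 000 iterations), and
the sampler was validated end-to-end against an independent MCMC
implementation of the identical model and priors (JAGS) on a small
instance, agreeing in posterior means, medians and interval endpoints to
Monte-Carlo precision.

Priors: each variance is inverse-Wishart/inverse-gamma with scale V = 1
and degree of belief ν = 1, i.e. IG(1/2, 1/2); fixed effects are
effectively flat (Normal precision 1e-8).  This prior has median ≈ 2.2
and little mass near zero, so a weakly identified component's posterior
sits visibly above zero even when the true value is zero — the
heritability checks therefore look at the posterior mode piling near
zero rather than at credible-interval coverage of an exactly-zero truth.
Credible intervals are equal-tailed 2.5%/97.5% quantiles.

DIC uses the Bernoulli-logit deviance conditional on the location
effects, `DIC = D̄ + p_D`, `p_D = D̄ − D(η̄)` with the plug-in at the
posterior mean linear predictor.  Component support is reported as
`ΔDIC = DIC(full) − DIC(without component)`; large negative values
support keeping the component.  A marginal-likelihood evaluator
(Gauss-Hermite product quadrature over whitened random effects,
dimension ≤ 6) exists purely to validate the latent model against brute
force numerical integration on tiny pedigrees.

## Reproductive skew

Per-class ARS descriptors use linear-interpolation quartiles (numpy
default, R type 7) and the population (divide-by-N) variance.  Under
that convention the moment reconstruction of Morisita's index,

    Σx(x−1) = N(Var + μ²) − Nμ,   I_δ = N·Σx(x−1) / (X(X−1)),  X = Nμ,

is an exact algebraic identity with the count-based form, which is what
lets published summary rows be audited without the raw counts; the
sample-variance convention is available via `ddof=1`.  The opportunity
for selection is `I = Var/μ²`.  Reconstructions from rounded published
moments inherit the rounding: class-level rows can differ from their
printed skew statistics in the second decimal, and such comparisons are
logged rather than asserted.

## Problem sizes and tolerances in the test suite

The suite runs entirely on synthetic data at the scale the analyses were
designed for: ~360-record tables for the behaviour GLMM, ~800–960-record
tables on ~300 males for the animal model, 3000-iteration chains for the
20-replicate recovery studies, 100 random pedigrees (≤ 60 individuals)
for the exact inbreeding oracle, and a 3-dimensional 81³ trapezoid grid
for the likelihood oracle (tolerance 1e-3 in log-likelihood).  Recovery
criteria are frequentist over seeds (e.g. ±2 SE coverage in ≥ 90% of 50
seeds; credible-interval coverage in ≥ 18/20 replicates) and were fixed
together with the generator defaults.

Passing these tests shows the estimators recover the truth under the
generator's assumptions — correct link functions, Normal random effects,
no immigration, no genotyping error, pedigree links missing only by
era.  They cannot certify behaviour under real-data pathologies such as
mis-assigned paternity, non-Normal year effects, or state-dependent
survival, none of which the generator emulates.

## Known limitations

* The Laplace ML likelihood differs from adaptive-quadrature likelihoods
  by O(1) constants in extreme-variance corners; AICc comparisons are
  between models fitted with the same approximation, which is the usual
  practice but not a guarantee against approximation-induced rank flips.
* The IG(1/2, 1/2) variance prior dominates weakly identified
  components at these sample sizes (posterior means near 0.2 for a true
  near-zero year variance); alternative priors are configurable per
  component but not explored systematically.
* Wald z-intervals are reported for averaged coefficients; the
  multimodel literature offers no exact small-sample recipe, and no
  significance test is attached to averaged estimates beyond these
  intervals.
* EPARS is taken as given in the input table; the package does not
  attempt to reconstruct which within-pair offspring were extra-pair.
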