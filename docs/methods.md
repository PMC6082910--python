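# Methods

## The model

The package analyses a battery of ordinal psychopathology items — by
default 51 items in four instrument blocks: 10 three-category
psychotic-experience items, 11 four-category negative-dimension items,
13 three-category depression items and 17 anxiety items — together with
one or more polygenic risk scores (PRSs) per respondent.

Each item *j* is treated as a coarsened observation of a latent standard
normal response *y\*ⱼ*: the observed category counts the thresholds
τⱼ,₁ < τⱼ,₂ < … lying below *y\*ⱼ* (the normal-ogive graded response
model).  Four measurement structures for the latent responses are
supported:

1. **uncorrelated** — four orthogonal group factors, one per block;
2. **unidimensional** — a single general factor;
3. **correlated** — four group factors with free correlations;
4. **bifactor** — one general factor loading on every item plus four
   orthogonal block-specific factors.

Everything is parameterized on the *delta* scale: latent responses have
unit variance, factor variances are fixed at 1, so loadings are
standardized and the residual variance of item *j* is
1 − λⱼᵀΨλⱼ.  This makes the omega reliability algebra exact and matches
the convention under which ordinal-SEM software reports standardized
solutions.

## Estimation

**Thresholds** are standard-normal quantiles of the (weighted)
cumulative category proportions.

**Polychoric correlations** use the two-stage estimator: thresholds are
fixed at their univariate values and each pairwise correlation maximises
the bivariate-normal contingency likelihood.  Rectangle probabilities
come from an Owen's-T evaluation of the bivariate normal CDF, and all
p(p−1)/2 pairs are updated simultaneously by damped Fisher scoring — the
per-pair expected information is available in closed form via the
Plackett identity ∂Φ₂/∂ρ = φ₂.  Missing responses are handled by
pairwise deletion.  The estimator is bounded at |ρ| ≤ 0.999; pairs that
hit the bound (e.g. an item paired with a recoding of itself) are
reported at the bound.

**Asymptotic covariance.**  Per-observation influence functions for
every pairwise correlation (thresholds held fixed — the usual two-stage
approximation; threshold-estimation noise is ignored) give both the
diagonal weight matrix and the full asymptotic covariance Γ of the
correlation vector.

**DWLS.**  Structure parameters minimise
Σ w(ρ̂ − ρ(θ))² with w the inverse asymptotic variances (a diagonal
weight matrix — the WLSMV convention, tractable at 51 items).  The
minimisation uses a trust-region least-squares solver with analytic
Jacobians; loadings are bounded at ±0.995 and a negative residual
variance raises a Heywood warning with the solution held at the
boundary.

**Test statistic.**  T = n·F is a quadratic form in the asymptotically
normal correlation deviations; its first two moments,
t₁ = tr(AΓ) and t₂ = tr((AΓ)²) with A the weighted residual projector,
give the Satterthwaite mean-and-variance adjustment: df\* = t₁²/t₂ and
T\* = T·t₁/t₂ (so E[T\*] = df\* under the model).  The degrees of
freedom are estimated, hence non-integer.

**Fit indices.**  RMSEA = √(max(T−df, 0)/(df·n)) — note the *n* (not
n−1) denominator, recorded in output metadata since conventions differ —
with a 90% CI from noncentral-χ² root finding; CFI and TLI against the
independence baseline (free thresholds, zero correlations) fitted on the
same data.

**Information criteria.**  AIC = −2ℓ + 2p, BIC = −2ℓ + p·ln n and
ssaBIC = −2ℓ + p·ln((n+2)/24) use the marginal (full-information)
likelihood of the ordinal responses, integrating over the factors with
scrambled Halton points mapped through the factor distribution (default
8000 points; the seed is recorded).  The likelihood is evaluated at the
DWLS estimates: those are consistent for the graded response model, so
the plug-in marginal likelihood supports model comparison without a
separate 100-parameter full-information optimisation; this is a
deliberate trade of a few likelihood units for orders-of-magnitude less
compute, and it leaves the structure ordering untouched at the sample
sizes the package targets.  Free-parameter counts are loadings +
thresholds + factor correlations.

## Reliability

From a bifactor solution, with ω the ratio of common variance (general +
specific) to total variance of the unit-weighted latent-response total
score, ω_H credits the general factor only; ω_S and ω_HS apply the same
ratios within one block, the hierarchical version crediting only that
block's specific factor.  Omegas are computed on the latent-response
(polychoric) scale from standardized loadings, not from raw sum scores —
the fitted model lives on that scale and the choice is recorded in the
output.

## Structural (MIMIC) model

The PRS enters as an observed covariate: every factor is regressed on
the standardized score simultaneously, η = γx + ζ, with residual factor
(co)variances chosen so each factor keeps unit total variance — γ is
therefore an SD change in latent trait per SD of PRS.  The item-item
polychoric matrix is augmented with item-PRS polyserial correlations
(two-stage ML, thresholds fixed) and the joint structure is fitted by
the same DWLS machinery.  Standard errors are sandwich estimates
H⁻¹ΔᵀWΓWΔH⁻¹/n with Γ from the stacked polychoric + polyserial
influence functions; CIs are Wald, P-values normal-theory.  Per-PRS
models are fitted separately (no mutual PRS adjustment), matching the
blocked reporting layout.

## Sensitivity analyses

**Permutation adjustment.**  MAP factor scores (posterior mode of the
factors given a respondent's responses, found by a damped, trust-region
Newton iteration vectorised over respondents; missing items are
marginalised by omission) are regressed on the PRS; the PRS vector is
permuted jointly against all outcomes, preserving the inter-factor
correlation.  Family-wise adjusted P-values use max-T step-down
(Westfall–Young): each observed |t| is compared to the permutation
distribution of the running maximum over the remaining family, with
p = (1 + #exceedances)/(1 + B) and monotonicity enforced.  The family is
one PRS × all factors; a different family definition can be had by
passing a different score matrix.

**IPW.**  Inclusion is modelled by logistic regression on auxiliary
covariates observed for everyone; included respondents are weighted by
1/p̂, truncated at the 99th percentile by default (logged in the
result).  Weights enter every estimating equation — thresholds,
polychoric/polyserial likelihoods and the sandwich — and are normalised
to mean one internally, so estimates are invariant to weight rescaling
and the all-weights-one path is numerically identical to the unweighted
one.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes:

- **Genotypes**: Hardy–Weinberg allele counts, per-SNP MAF uniform in
  (0.05, 0.5); no LD, stratification or relatedness (out of scope).
- **PRS truth**: discovery-style summary statistics with ~30% causal
  SNPs; the true score is the standardized all-SNP weighted allele sum.
  Independent weight draws across traits give weakly correlated PRSs.
- **Factors**: each factor is Σβ·PRS + residual with residual variance
  set for unit total variance; residuals are independent, so the
  bifactor truth is orthogonal and the ω algebra is exact.  Default
  effects are small (|β| ≈ 0.01–0.07), as in adolescent-cohort PRS work.
- **Items**: graded-response draws under the delta parameterization.
  Default general loadings U(0.5, 0.8) and specific loadings U(0.3, 0.6)
  (jittered deterministically from the seed) span the
  strong-general/weak-specific pattern such batteries show; default
  thresholds are right-skewed (most respondents in the lowest category),
  as symptom items are.  The anxiety block's category count is
  configurable (default 3) since instrument response formats vary.
- **Missingness**: an "advantage" covariate correlated with the general
  factor and an independent sex indicator drive logistic inclusion
  (defaults: logit = 0.4 + 0.3·female + 1.2·advantage, advantage loading
  −0.5).  Missingness is MAR given covariates, never given the factors
  directly, so IPW on those covariates is a consistent correction by
  construction.

What the generator does *not* emulate: real-instrument marginals,
LD structure, item-level response styles, longitudinal drift.  Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to violations real cohort data may show.

## Study designs used by the property tests

Replication sizes were chosen to keep each study comfortably inside a
desk-scale compute budget while leaving Monte-Carlo error well below the
assertion margins: loading recovery uses 20 cohorts of n = 3000; model
selection 20 cohorts of n = 2000 with 2000 integration points;
structural recovery and CI coverage 50 cohorts of n = 3000; permutation
FWER 200 null datasets of n = 500 with 200 permutations.

The IPW study needs special comment.  Under paper-scale effects
(|β| ≈ 0.06) Bernoulli-logistic selection on a moderately correlated
covariate shifts the estimand by only ~1% of β (the Pearson–Lawley
shrink factor √(1 + ρ²(v−1)) stays near 1), which is unmeasurable
against sampling noise at any reasonable n.  The bias-reduction study
therefore uses a design where the selection bias is identifiable:
covariate loading 0.95 on the general factor, inclusion logit
0.5 + 2.2·z, β_general = 0.5.  Under that design the unweighted
estimate is attenuated by ≈ 0.08 while IPW removes most of it;
truncation at the 99th percentile trades a small residual bias for a
visibly smaller variance.

## Numerical choices and degenerate inputs

- Bivariate normal CDF via Owen's T; |ρ| clipped at 0.99995; exact
  zeros in the arguments nudged by 1e−12 (error O(1e−12)).
- Polychoric scoring: start at the cell-moment Pearson correlation,
  step damping by likelihood backtracking, convergence at |Δρ| < 1e−8,
  bound ±0.999.  Items with a single observed category raise
  (unidentifiable).
- DWLS: gradient-based convergence (gtol 1e−10); non-convergence raises
  with the last gradient norm.
- MAP scores: interval probabilities evaluated in the stable tail,
  curvature clipped to the concave side, Newton steps capped at norm 4;
  all-missing respondents get NaN scores.
- RMSEA with df = 0 (saturated model) is reported as 0 with a flag.
- Zero-variance PRSs, constant items, non-positive weights and
  separation in the IPW logistic model raise informative errors.

## Known limitations

- Threshold-estimation noise is ignored in Γ (standard two-stage
  practice); standard errors can be mildly optimistic in very small
  samples.
- Information criteria use plug-in DWLS estimates, not a full
  full-information re-fit; absolute IC levels are slightly conservative
  even though comparisons are stable.
- No LD-aware SNP selection (clumping) in core scope; an optional
  pruner was considered and left out because discovery-side construction
  details are study-specific.
- Bifactor models with single-item blocks are unidentified; the package
  does not guard against every such specification.
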