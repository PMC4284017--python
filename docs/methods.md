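# Methods

## Model

Animals are marked either at fledging (age 0, entering the *pre-return*
state) or at age 1+ (entering the *returned* state; their true age is
unknown and they are assigned the oldest age class throughout).  Latent
dynamics per annual interval t → t+1, conditional on first capture:

1. survive with probability ϕ (age-class- and covariate-resolved);
2. if pre-return at arrival age a, return for the first time with
   probability Ψ(a); returned animals never revert (reverse transition
   fixed at 0); dead is absorbing;
3. be detected at the arrival occasion with probability p if returned,
   0 if pre-return or dead.

The survive-then-transition ordering with detection at arrival is the
convention of the multistate software this package interoperates with;
the likelihood conditions on marking, so the marking detection itself
contributes nothing.  A fledgling's first interval begins at tagging
shortly before fledging and is treated as an ordinary one-occasion
interval.  Deviance is defined as −2·log-likelihood, not relative to a
saturated model; every selection statistic used downstream (ΔAICc/QAICc,
LRT, ANODEV, R²_DEV) depends only on deviance *differences* between
models on the same data, which are invariant to that choice.

All probabilities use a logit link.  Factors are reference-coded
(interval 1 as reference for year factors; age-class intercepts carry no
global intercept), so the structural coefficient count k equals the
design's column count; a numeric rank check on the stacked design rows
flags non-identifiable structures.  Fixed parameters (Ψ above the
maximum first-return age, pre-return detection, the reverse transition,
and the optional `p(=value)` recapture) never enter the coefficient
vector.

Ψ age trends (`linear`, `ln`) are applied on the logit scale —
logit Ψ(a) = b₀ + b₁·a or b₀ + b₁·ln a — which keeps probabilities in
(0,1) for any coefficients.  Additive age+time survival is one shared
year factor plus age-class intercepts; interactive is a separate year
factor per class.  Individual fledging mass enters the fledgling age
class only.

## Standardization

Covariates are z-scored, (x − x̄)/s with the sample (n−1) standard
deviation, so regression coefficients are comparable effect sizes per
1 SD.  Annual covariates are standardized across the study occasions;
individual fledging mass against the pooled mass distribution of all
retained fledglings (not per cohort), keeping within- and between-year
contrasts on one scale.  Slopes are de-standardized by dividing by the
stored scale.  Fledglings lacking a mass are removed before analysis
(`filter_missing_mass`); if a mass-covariate model is nevertheless fitted
to data containing them, their design entry is 0, i.e. the mean —
filtering first is the supported path.

## Estimation

The exact likelihood is a forward recursion over
{pre-return, returned, dead}, vectorized over animals and over a batch
axis of coefficient vectors.  Gradients are batched central finite
differences (step 10⁻⁵·(1+|β|)) evaluated in a single array pass;
optimization is L-BFGS-B from `n_restarts` starts (zero vector or a warm
start, plus N(0, 0.5) jitters), keeping the best optimum.  Convergence is
declared at ‖g‖∞ ≤ tol·max(1, |f|) with default tol 10⁻⁵ — the noise
floor of finite-difference gradients at these sample sizes; a tighter
absolute gradient norm is unattainable and would only mislabel converged
fits.  The covariance is the inverse of a batched central-difference
Hessian (step 10⁻⁴·(1+|β|)) of the negative log-likelihood; a
non-invertible or non-positive-diagonal Hessian falls back to a
pseudo-inverse and clears the `converged` flag.

Effective sample size for AICc is the number of encounter histories —
the defensible choice when individual covariates preclude pooling, and
it only affects the small-sample correction term.
AICc = dev + 2k + 2k(k+1)/(ess−k−1); QAICc divides the deviance by ĉ and
charges one extra parameter for estimating it.

First-return parameters at the highest estimable age can sit on the
boundary (Ψ̂ → 1) when few birds remain unreturned; such coefficients
drift to large logits with large SEs.  Short study spans aggravate this;
the ln/linear trends, which pool information across ages, are the remedy
the candidate set provides.  Similarly, annual survival estimates whose
logit-scale SE exceeds 3 are flagged non-identifiable and excluded from
variance-component analysis (a package constant mirroring the practice of
dropping unidentifiable cohort-years).

## Overdispersion (median-ĉ)

Datasets are simulated from the fitted global model at a grid of true ĉ
values (default 7 equally spaced points across bounds 1.0–4.0, 100
replicates split evenly), each refitted warm-started at the global MLE,
and a logistic regression of the event "simulated deviance-ĉ exceeds
the observed deviance-ĉ" on true ĉ is solved for its 0.5 crossing,
clamped to the bounds; ĉ > 3 flags lack of fit.  Deviance-ĉ is
(model deviance − saturated multinomial deviance)/(ess − k), the
saturated term computed over (mark class, cohort, history) cells
ignoring individual covariates; only its monotonicity in overdispersion
matters, since the crossing compares like with like.  Under perfect
separation or a non-positive slope the crossing falls back to linear
interpolation of per-grid exceedance fractions.

Overdispersion is *injected* by cluster-shared fates: animals within a
cohort are partitioned into clusters of size c that share survival and
first-return outcome draws, while detections stay independent (keeping p
estimable).  Integer c inflates the variance of cohort survivor counts
by ≈ c without moving marginal rates; non-integer c mixes adjacent
integer sizes.  This is an explicit, testable mechanism for a procedure
usually treated as a black box; it is validated by its own calibration
(ĉ near 1 without clustering, within [1.5, 2.5] at c = 2).

## Covariate selection (step-up)

Step 1 fits the constant base (age-class intercepts only).  Step 2 tests
individual covariates in isolation by LRT (χ² = ΔDEV, df = Δk).  Each
later step fits every remaining annual covariate on top of the current
model; ANODEV compares constant ⊂ covariate ⊂ time models, where the
"constant" reference is the current model and the time reference is the
current model plus full additive year effects, refitted each step;
R²_DEV = [DEV(.)−DEV(cov)]/[DEV(.)−DEV(t)].  The covariate with the
largest R²_DEV is retained if R²_DEV > 0.20 (ties broken by fewer
parameters, then label order), with the ANODEV p reported as a
diagnostic; otherwise the procedure stops.  Retention deliberately
follows the R² rule rather than the p-value, so a borderline
p with R² at the threshold still proceeds.  Additive vs interactive
entry of each annual covariate is chosen by QAICc between the two forms;
a term's form can be forced by configuration for extra-statistical
reasons (e.g. strong prior evidence of an age-specific predation
effect).  Retained coefficients are finally verified by Wald CIs on the
logit scale using the ĉ-inflated covariance.

## Derived quantities

- Survival predictions: logit-linear predictor at given covariate values
  (raw scale when a standardizer is supplied), delta-method CI.
- Cumulative first return: C(a) = 1 − Π_{i≤a}(1 − Ψᵢ); reaches 1 one age
  past the maximum.
- Process variance: intercept-only random-effects moment estimator —
  find σ² ≥ 0 and weighted mean μ̂ (weights 1/(σ²+v_t)) with weighted SS
  equal to T−1, by Brent root-finding, truncated at 0; shrunken annual
  estimates μ̂ + σ²/(σ²+v_t)·(θ_t−μ̂).  Annual inputs come from the
  additive-time model's year terms on the probability scale with
  delta-method variances.
- Sensitivities: S = β·ϕ(1−ϕ), the partial derivative of survival per
  1 SD of the covariate, evaluated at standardized-covariate zero (the
  means) and the class's fitted survival.  Per-SD units keep the values
  comparable across covariates; de-standardized slopes are available
  separately.
- Fledging-mass cohort ANOVA: one-way fixed effects via scipy, with the
  exactly-degenerate equal-means case clamped to F = 0.

## Synthetic data

The generator emulates the study conditions: 10 annual occasions; one
fledgling cohort (default 150, mass ~ N(3.28, 0.35²) kg, rounded to
0.05-kg weighing precision) and one adult batch (default 100) marked per
occasion, approximating the study's totals of ~1070 fledglings and ~966
adults; fledging-year survival 0.33 and 0.89 thereafter; first return
(0.10, 0.55, 0.75, 0.95) by age, certain beyond; detection 0.99/0.88/0.15
by gateway effort with one failed (0-day) and one intermittent (50-day)
season mimicking the observed effort pattern; annual covariates drawn
independently standard normal (optional AR(1)), predation pressure as a
rounded positive normal count.  Truth records carry every generating
parameter, the realized per-animal rates and full latent paths, and can
emit the generating coefficient vector on a fitted model's layout for
recovery scoring.

What the generator does **not** emulate — and hence what passing tests
do not establish about field data: tag loss and tag-induced mortality,
individual heterogeneity beyond fledging mass (frailty), within-season
attendance structure, non-independence between covariates and cohort
sizes, and any real confounding between gateway effort and survival.
Calibration results (coverage, type-I error, ĉ recovery) are statements
about the model's internal consistency at the stated scales.

## Problem sizes used in the checks

The automated checks run at deliberately chosen scales: likelihood
oracle, 1000 random history/parameter pairs with ≤ 5 occasions; CJS
reduction, 501 adults over 4 occasions against an m-array oracle;
parameter recovery, 20 datasets (tests) / 10 (script) of ~1500
fledglings + ~1000 adults over 10 occasions; LRT calibration, 200
(tests) / 100 (script) null replicates; step-up first-pick, 50 / 30
replicates at a strong (0.8 per SD) single active covariate; median-ĉ,
10 / 6 trials per condition at 25 replicates each; variance components,
50 replicates of 9 annual estimates at σ = 0.12.  These sizes give the
Monte-Carlo resolution the corresponding assertions need while keeping a
full run to a few minutes on one CPU.

## Known limitations

- Wald intervals only; no profile likelihood or Bayesian posterior.
- The structural k is the reference-coded coefficient count; software
  that counts *estimable* parameters on a given dataset can differ for
  confounded time-dependent structures.
- Median-ĉ inherits the cluster-fate mechanism's notion of
  overdispersion; other misfit shapes (trap response, heterogeneous p)
  are not targeted.
- No breeding/interbreeding season split, dead recoveries, memory
  models, or multi-letter state encodings (the unobservable state is
  never detected, so histories are binary).
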