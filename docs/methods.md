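# Methods

## Model

Let x be the vector of maternal determinants in model-ready units (age in
years, height in centimetres, pre-pregnancy weight in kilograms, five 0/1
flags; the subsample variant adds three ultrasound biometry z-scores).  The
latent foetal-growth variable η and the indicators are

    η   = γ'x + ζ,        ζ ~ N(0, ψ)
    BWZ = ν₁ +   η + ε₁,  ε₁ ~ N(0, θ₁)
    BLZ = ν₂ + λ·η + ε₂,  ε₂ ~ N(0, θ₂),  ε₁ ⊥ ε₂ ⊥ ζ

with the BWZ loading fixed at 1 (the latent variable is scaled in
birth-weight z-score units), indicator intercepts free, no structural
intercept for η, and covariates uncentred.  This identification makes the
latent scale interpretable: the raw factor scores sit around γ'x̄ rather
than zero.

Two determinants — pre-pregnancy elevated blood pressure and insufficient
gestational weight gain — are treated as endogenous: each receives a linear
equation on all remaining (exogenous) determinants with its own residual
variance ω, and those residuals are conditionally independent of each
other.  Which determinants feed these two equations is a modelling choice
here (all exogenous ones, fully configurable); nothing in the data schema
pins it down.  Binary endogenous variables are modelled linearly — the
linear-probability convention of covariance-structure software.  Their
Bernoulli residuals are heteroskedastic, which the robust corrections
absorb (coefficients remain consistent because the moment structure is
linear); this is a documented limitation, not an oversight.

## Estimation

Estimation is maximum likelihood conditional on the exogenous determinants
(fixed-x).  Writing m = (elevated_bp, insufficient_gwg, BWZ, BLZ) and
z = (1, x_exo), the model implies a reduced form m = A(ϑ)z + e with
e ~ N(0, Σ(ϑ)); the fit minimizes the discrepancy

    F(ϑ) = log|Σ(ϑ)| + tr(Σ(ϑ)⁻¹ R(ϑ)) − log|Σ_sat| − p

where R(ϑ) is the empirical second moment of the residuals and the
saturated reference is the unrestricted multivariate regression of m on z.
Because the likelihood factorizes over the exogenous block, this gives the
same point estimates as a joint fit with saturated exogenous moments.
T_ML = (n−1)·F̂; degrees of freedom are the non-redundant sample moments
(reduced-form coefficients plus residual covariances) minus free
parameters — 38 − 30 = 8 for the population model, 50 − 39 = 11 for the
subsample model, and 1 for the direct-effects alternative.

Numerics: quasi-Newton (L-BFGS-B) iteration on a standardized internal
parameterization (coefficients re-expressed for centred, unit-scale
exogenous covariates — the raw surface is severely ill-conditioned because
uncentred height in centimetres makes the intercept and slope directions
nearly collinear), with a cheap forward-difference gradient.  Starting
values are deterministic least-squares decompositions: β from OLS of each
endogenous equation, γ from OLS of BWZ on all determinants, λ from the
covariance ratio of BLZ with the fitted structural composite, ψ/θ from the
residual-covariance decomposition.  Convergence requires a central-
difference gradient max-norm below 1e-5 in the standardized space (function
tolerance 1e-12, at most 500 iterations per pass with up to two polishing
passes).  Variances are bounded below at 1e-8; an estimate at that floor is
reported as a Heywood case with an explicit warning, never silently.  Under
the default calibration θ₁ is small (≈0.087), so roughly 2% of cohorts of
n ≈ 1250 genuinely place the ML optimum on the θ₁ = 0 boundary; a
brute-force likelihood check confirms these are true optima.

## Robust corrections

The Satorra–Bentler machinery operates on the sample-moment vector
s = (vec Â, vech Σ̂) of the saturated regression.  Γ, the empirical
asymptotic covariance of s, is the average outer product of per-row
influence functions (a function of fourth-order moments).  With Δ the
Jacobian of the implied moments at the estimates and V the normal-theory
weight matrix (block-diagonal: S_zz ⊗ Σ̂⁻¹ for the coefficients and
½D'(Σ̂⁻¹⊗Σ̂⁻¹)D for the covariances), the robust parameter covariance is
the sandwich (Δ'VΔ)⁻¹Δ'VΓVΔ(Δ'VΔ)⁻¹/n, the scaling factor is
c = tr(UΓ)/df with U = V − VΔ(Δ'VΔ)⁻¹Δ'V, and T_SB = T_ML/c.  Under
multivariate normality Γ → V⁻¹ and c → 1 (verified at n = 50 000).  For a
saturated model (df = 0) the scaling is undefined and T_SB is reported as 0
with a note.

Fit indices follow the standard formulas — RMSEA = √(max(T−df,0)/(df(n−1))),
CFI and TLI against the independence baseline (endogenous variables
mutually uncorrelated, free means and variances, no covariate dependence),
BIC = −2ℓ̂ + k·log n — computed twice, once with T_ML and once with T_SB
inserted in the same formulas (one of several published conventions for
"scaled" indices; chosen for simplicity).  SRMR is the root mean square of
standardized residuals over the joint covariance of all modelled variables,
covariance block only, no mean residuals.

Explained variance: R²_indicator = λ²Var(η)/(λ²Var(η)+θ) with
Var(η) = γ'Φγ + ψ and Φ the sample covariance of the determinants;
R²_latent = γ'Φγ/(γ'Φγ+ψ).  Two-sided Wald tests from robust standard
errors define significance at α = 0.05 throughout.

## Factor scores and outcome models

The default factor score is the regression (empirical-Bayes) predictor
E[η | indicators, x] = γ'x + ψλ'V_y⁻¹(y − ν − λγ'x) with
V_y = λλ'ψ + diag(θ), linear in the data and shrunken towards the
structural prediction; Bartlett scores (unshrunken) are available behind a
flag.  Standardization subtracts the analysis sample's mean and divides by
its SD (denominator n−1).

Outcome models are ML logistic regressions with Wald 95% intervals:
each perinatal outcome on (a) the standardized latent score, unadjusted —
the score already aggregates the measured determinants — and (b, c) BWZ or
BLZ with the fixed eight-determinant adjustment set.  First-stage
uncertainty in the score is ignored, exactly as in a two-step analysis;
consequently the latent-score odds ratio is mildly attenuated towards 1
relative to the generating slope (the score's correlation with the true
latent is ≈0.95 under the default calibration, so a generating odds ratio
of 0.50 is recovered as ≈0.52 at large n).

## Synthetic-cohort generator

The generator emulates the statistical structure the analysis assumes,
stage by stage: (1) continuous covariates — age ~ Normal(25, 6.9) clipped
to [13, 49], height ~ Normal(1.57 m, 0.059), weight ~ logNormal matched to
a 57.3 (51, 65) kg median/IQR; (2) exogenous binaries by thresholding
correlated latent normals (Gaussian copula) at prevalences 0.397
(primiparity), 0.052 (smoking), 0.075 (malaria), with modest dependence
(younger age strongly linked to first birth, height-weight correlation
0.4); (3) elevated blood pressure (0.126) and insufficient weight gain
(0.335) as Bernoulli draws on linear-probability means truncated to
[0.01, 0.99]; (4-5) η and the indicators from the structural model above;
(6) outcomes as Bernoulli(logistic(a + b·standardized η)) with b = log 0.5
for preterm birth and hospital stay >3 days and b = 0 for reanimation and
formula prescription, intercepts solved by Gauss–Hermite quadrature so the
marginal prevalences hit their targets; (7) optional columnwise
missingness (none by default — the default cohort is the complete-case
population).

Structural defaults are the fitted values of the analysis the package
re-implements: γ = (0, 0.01/cm, 0.02/kg, −0.22, −0.29, −0.55, −0.17,
−0.36), λ = 0.82 (population variant); the subsample variant adds biometry
effects (0.18, 0.28, 0.11) and uses its own column of estimates.  The
printed age coefficient "−0.00" is taken as exactly zero, which doubles as
the null parameter in the power-calibration checks.  The free quantities no
table pins down — ψ, θ, ν, and the covariate dependence — are fixed once by
`analysis/00_calibrate_generator.py`: a 2-million-row covariate draw gives
Φ, and ψ, θ₁, θ₂ are solved so the implied variance shares equal the
targets (R²_latent = 0.185, R²_BWZ = 0.883, R²_BLZ = 0.537; subsample
0.438/0.81/0.52), then frozen as JSON shipped with the package
(ψ = 0.532, θ = (0.087, 0.379) for the population variant).  The default
seed 20150701 (the cohort recruitment start date) is always overridable.

Two switches support calibration studies: `gaussian_covariates` replaces
every binary mechanism with a jointly normal one so the data exactly
satisfy the model's normality assumption (used for the χ² size check), and
`skewed_residuals` makes ε shifted-lognormal with skewness ≈ 2 and excess
kurtosis ≈ 8 — the conventional moderate non-normality condition in
robustness simulations (used for the sandwich-vs-naive contrast).  A
`direct_effects` mode generates the indicators from two deliberately
non-proportional coefficient vectors with no latent variable, for the
model-comparison study.

What the generator does not emulate: real measurement processes (digitized
records, rounding, recall error), informative missingness, gestational-age
estimation error, sex differences, or any nonlinearity in the structural
relations.  Passing tests therefore show that the estimator recovers the
model under its own assumptions plus realistic marginals and non-normality
— not that the model is correct for any particular cohort.

## Simulation designs used by the test suite

Chosen as the smallest designs whose Monte-Carlo error is well below the
tolerances they check: oracle equivalence on a fixed n = 500 cohort (1e-4
per parameter against an independently coded likelihood); parameter
recovery and robust-CI coverage over 500 cohorts of n = 1249 (bias band
0.02, coverage band [0.93, 0.97]); χ² size over 1000 normal cohorts of
n = 1000 (rejection band [0.035, 0.065]); SE calibration over 500 skewed
cohorts of n = 1000 (10% band); BIC model selection over 200 cohorts per
generating model; outcome-effect recovery at n = 10 000 and type-I error
over 500 cohorts of n = 2000; power size/closed-form checks at 300 and
2000 replicates.

## Known limitations

* Binary endogenous covariates are modelled linearly; their coefficients
  are linear-probability effects, not log-odds.
* Two-step outcome modelling ignores first-stage uncertainty and incurs
  mild attenuation (see above).
* With θ₁ calibrated near zero, its naive (normal-theory) standard error is
  close to calibrated even under skewed residuals — the fourth-moment
  contribution to its sampling variance scales with θ₁² — so the
  robust-vs-naive contrast is expressed on θ₂ and on the Bernoulli residual
  variances, and boundary (Heywood) solutions occur in a small share of
  replicates and are flagged.
* The SB-scaled fit indices insert the scaled statistics into the unscaled
  formulas; other published conventions exist.
* WLSMV/categorical-indicator estimation, FIML for missing data, multi-group
  models and Bayesian estimation are out of scope.
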