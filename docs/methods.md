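# Methods

## Models

**Cox proportional hazards.** For predictors x₁…x_L the hazard is
λ(t|X) = λ₀(t)·exp(β₁x₁ + … + β_Lx_L).  Coefficients maximize the partial
likelihood with the Efron tie correction (Breslow available); the
covariance is the inverse observed information at the maximum, and
AIC = 2k − 2·logPL.  The biomarker T may enter linearly, quadratically
(T and T²), or as log(T) or √T (the latter two require positive T);
covariates enter reference-coded, with optional biomarker-by-covariate
interactions.  The baseline hazard is never needed for efficacy — every
quantity downstream is a hazard ratio — but a Breslow cumulative-hazard
estimator is exposed for simulation checks.

Newton–Raphson with step-halving stops when max|score| < 1e−8 or the
relative log-likelihood change is below 1e−10, with at most 50 iterations.
Monotone likelihood (separation) is detected by a scale-free magnitude
check (|β|·sd(x) > 10): such fits carry `diverged=True`, warn, and are
never silently reported as converged.

**Competing risks.** Cause-specific fits treat competing events as
censored at their times (noninformative-censoring assumption).  The
Fine-Gray subdistribution fit instead keeps a subject failing from a
competing cause at time s in the risk set at every later target-event time
t, weighted by G(t−)/G(s−), where G is the Kaplan–Meier estimate of the
censoring distribution pooled across arms.  Ties use the weighted Efron
analogue, so the fit reduces exactly to the Cox fit when no competing
events exist.  The reported covariance is the inverse weighted information
matrix; it agreed with `cmprsk::crr` point estimates to six decimals in
development checks, while `crr`'s robust (sandwich) standard errors are
somewhat larger.  Because the objective is a pseudo-likelihood, the
Fine-Gray "AIC" is comparable only across Fine-Gray fits of the same cause
on the same data.

**Cumulative incidence.** Nonparametric per-cause CIFs accumulate
S(t_{j−1})·d_cj/n_j at each event time while S is the any-cause
Kaplan–Meier; by construction S(t) + Σ_c CIF_c(t) = 1 at every step.

**PH diagnostic.** Per-term score test for a linear association of scaled
Schoenfeld residuals with time (identity transform).  The variance of the
score uses the exact profiled form Σg²V_k − (ΣgV_k)·I⁻¹·(ΣgV_k), which
matches `survival::cox.zph` numerically; type-I error calibrates to the
nominal 5% level in the test suite.

## Correlates assessment

Stage 1 fits biomarker-only candidates (linear, quadratic) and keeps the
lower-AIC form unless the extra parameter buys at most 2 AIC points, in
which case the smaller model is kept (so a 426.0-vs-428.0 contest selects
the linear form).  Stage 2 pits the winning form against the same form
adjusted for all supplied covariates and their biomarker interactions,
selected by the same rule.  The biomarker is a correlate of risk (CoR) if
the joint likelihood-ratio test over *all* biomarker-involving terms of the
final model is significant at α (default 0.05).  For the single-term linear
model this joint LRT and the per-coefficient Wald test coincide
asymptotically.  When interactions are present, a per-subgroup joint Wald
test of the biomarker contrasts at each covariate level is reported,
labelled as such (the subgroup-level test has no canonical form; this is
the package's choice).

The Prentice correlate-of-protection (CoP) criterion adds vaccination
status to the final CoR model: the biomarker is a CoP if vaccination does
not significantly improve the fit (LRT p ≥ α) while the biomarker terms
remain jointly significant in the augmented model.  With multiple
correlated titer columns, multicollinearity is screened with VIFs and the
analyst chooses the average of centered/scaled log2 titers (the default
summary) or principal components as T.

## VE estimation

The risk curve ρ(T|X) = exp(lp(T,X) − lp(T_ref,X)) defaults its reference
to the median of all observed biomarker values; the reference only
anchors plots — it cancels in VE.  Subgroup VE averages ρ over each
vaccinated subject's own biomarker and covariate vector, divided by the
same average over controls; subgroup membership is defined by the
conditioning covariate only, and any vaccination-status column of an
augmented fit is zeroed so both arms are evaluated on the same curve.

The 95% CI resamples subjects with replacement *within each arm* of the
subgroup (stratification keeps both averages defined in every replicate)
and draws one coefficient vector per replicate from N(β̂, Σ̂) — joint
propagation of data and parameter uncertainty.  The CI is the empirical
2.5th/97.5th percentile of the replicate VEs using the inverse-ECDF
quantile convention; n_bootstrap defaults to 1000; a singular Σ̂ collapses
to a point mass with a warning.  Everything is reproducible from the seed.

Comparators: the case-count estimate uses the incidence-rate ratio with an
exact CI from the conditional-binomial argument (given the total case
count, vaccine-arm cases are binomial; Clopper–Pearson bounds map
monotonically to the rate ratio — the method is a package choice and is
swappable).  Zero control-arm cases with vaccine-arm cases yield a −∞
point; zero cases in both arms is an error, not a number.  The
vaccination-status model (vaccination, subgroup covariate, interaction)
gives the classical model-based VE with a Wald CI on the log-HR scale.

## Synthetic trials

The generator emulates an immunogenicity sub-study: two arms, one binary
baseline covariate (Bernoulli prevalence), biomarker normal per arm on the
log2 scale (optionally degenerate at 0 for controls, reproducing the
fold-rise convention), event times by inverse transform from an
exponential-baseline PH hazard per cause, independent competing causes,
and censoring as min(exponential dropout, administrative horizon).
Defaults describe a realistic proof-of-concept setting: 300 subjects per
arm, three-year follow-up (1095 days), baseline hazard 1e−4/day (≈10%
attack rate), biomarker effect β = ln 0.5 per unit log2 titer and a one-unit
immunogenicity shift between arms — i.e. a true VE of 50% and 30–80 cases
per trial.  The closed-form oracle uses the normal moment-generating
function, VE = (1 − exp(βΔμ + β²(σ_v²−σ_c²)/2))·100, with adaptive
quadrature (tolerance 1e−8) for the quadratic link.

What the generator does **not** emulate: seasonal or time-varying
incidence, measurement error in the biomarker, time-dependent biomarker
trajectories (durability), informative dropout, and non-PH effects.
Passing tests therefore demonstrate correctness of the estimators under
their own assumptions, not robustness to those violations.

## Numerical choices and edge cases

- Sample standard deviations use the n−1 denominator throughout.
- Normality screening in the group-comparison router uses a KS test
  against a normal with estimated moments at significance 0.05; variance
  homogeneity by Bartlett's test; fallback order t-test → Welch →
  Mann–Whitney U.
- Arm labels are normalized case-insensitively ({vaccine, vaccinated} /
  {control, placebo}); anything else is an error, not a guess.
- Missing values in required columns are handled complete-case and the
  dropped count is reported; rows missing a baseline titer are incomplete
  cases (no imputation).
- Perfectly collinear predictors report infinite VIF rather than failing.
- Cause codes must be contiguous {0,…,K}; relabeling causes consistently
  leaves cause-specific fits unchanged (tested).
- Linear predictors are clipped at ±500 before exponentiation to avoid
  overflow in diverging fits; the divergence flag governs interpretation.

## Test-suite problem sizes

Deterministic oracles run at 4–8 subjects (grid scans at step 1e−4).
Stochastic properties use: 100 trials of 3000 subjects for coefficient
recovery; one 40000-subject trial for large-sample VE convergence;
200 trials (600 subjects, B = 200) for CI coverage; 500 null replicates of
n = 150 for LRT/PH calibration; 100 trials (600 subjects) for the
precision comparison; module-level power/mediation checks run at 20–25
replicates of 800–1000 subjects.  These sizes are the package's chosen
balance between Monte-Carlo error and a test suite that runs in about a
minute.

## Known limitations

- Time-varying coefficients, frailty and stratified baselines are out of
  scope; the PH diagnostic is the guard rail.
- The Fine-Gray covariance omits the robust variance correction for the
  estimated weights (standard errors are mildly anti-conservative with
  heavy censoring).
- The Prentice criterion loses power when the vaccine arm has few cases;
  a non-significant vaccination coefficient is then weak evidence, which
  is why the VE prediction itself is reported alongside the verdict.
- The percentile bootstrap CI can slightly undercover (observed ≈92–96%
  at nominal 95% in the suite's conditions).
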