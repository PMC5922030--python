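# Methods

`cd4joint` implements a Bayesian shared-parameter joint model for a
longitudinal overdispersed count outcome (the per-visit CD4 cell-count
change of HIV patients on HAART) and a time-to-event outcome (the number of
follow-up visits until the patient defaults from treatment), together with
a synthetic cohort generator with exactly the same latent structure, so
that every stage of the analysis can be validated by parameter recovery.

## The model

**Longitudinal submodel.** For patient *i* at follow-up visit *j* the
CD4-change count is conditionally Poisson on a log link:

    log mu_ij = x_ij' beta1 + nu0_i + nu1_i t_j + eps_ij
    y_ij | eps_ij ~ Poisson(mu_ij)
    eps_ij ~ N(0, b_i),   log b_i ~ N(0, sigma_b^2)
    (nu0_i, nu1_i) ~ N2(0, Sigma_nu)

The visit-level normal perturbation `eps` makes the count marginally
overdispersed (a Poisson–log-normal distribution); this is the generative
counterpart of a quasi-Poisson fit, which has no sampling distribution of
its own. The patient-specific dispersion `b_i` ("heterogeneous variance")
lets patients differ in how erratically their CD4 change fluctuates; fixing
`b_i = exp(0)` for everyone gives the homogeneous-variance model.

**Survival submodel.** Time to default, on the follow-up-visit clock, is
Weibull proportional hazards with the shared latent term inside the
exponent:

    h_i(t) = phi rho t^(rho-1) exp( x_i' beta2 + W2_i )
    W2_i = tau0 nu0_i + tau1 nu1_i + tau_b log b_i + u_i,  u_i ~ N(0, sigma_nu^2)

A multiplicative (log-hazard-additive) placement of `W2` is used; an
additive-on-the-hazard placement would permit negative hazards. `rho < 1`
means the default rate decreases as follow-ups accumulate. `tau0`/`tau1`
link the CD4 trajectory's level and slope to the hazard of defaulting,
`tau_b` links its volatility, and `u` is a residual frailty. Setting all
loadings and the frailty variance to zero decouples the two submodels
exactly (a tested identity).

**Time coding.** Both submodels share one clock: the follow-up-visit
number. The longitudinal time covariate (and the random slope) is the visit
index with its origin at the first modelled change visit, so coefficients
are per follow-up visit — the units in which the analysis interprets the
time effect (a coefficient of 0.021 is a 2.1% increase per visit). The
origin matters under informative dropout: anchoring it mid-study would let
a steep slope mimic a low early level for patients observed only briefly,
confounding the intercept and slope effects.

**Change convention.** The first on-treatment visit is the reference
measurement; changes are modelled from visit 2 on, defined only between
adjacently observed visits (no imputation across gaps). Changes are
generated as non-negative counts, consistent with the count-model treatment
of the outcome; real CD4 changes can be negative, which the generator does
not emulate.

## The synthetic cohort generator

Defaults reproduce the reference cohort's published characteristics:
covariate marginals (50.6% female, 40.9% rural, 68.2% good adherence, …;
age/weight/baseline-CD4 log-normal with matched median and quartiles, age
floored at 18), the published joint-model fixed effects and variance
components (intercept 4.130, age −0.036, Var(nu0) = 0.862, Var(nu1) =
0.011, Cov = −0.064, tau1 = −2.324, tau_b = 0.051, rho = 0.864), a
monthly-then-quarterly visit schedule over a 20-visit (four-year) window,
administrative censoring at the window's end, and 10% MCAR dropout of
post-baseline visits.

Values the source analysis never reports are fixed once here:

- time coefficient 0.021/visit (the value the analysis text itself
  interprets as "2.1% per visit"; the alternative printed value of 0.121
  would make late-study changes average ~150 cells/mm^3/visit,
  contradicting the cohort's own observed change scale of ~16);
- survival intercept −2.2, calibrated so that roughly a third to a half of
  the cohort defaults within the administrative window (the printed
  survival intercept would make virtually everyone default before the first
  follow-up, impossible in a cohort defined by having at least two visits);
- sigma_b^2 = 0.25 (log-dispersion spread: most patients' dispersion
  within a factor ~2.7 of the median), tau0 = −0.3 (higher CD4-change level
  mildly protective), frailty variance sigma_nu^2 = 0.25 (residual hazard
  heterogeneity within a factor ~e of the median).

The generator is a pure function of its arguments and a seed. What passing
recovery tests on it demonstrate is internal consistency — the fitters
recover the parameters of data generated by the model they assume. They do
not demonstrate robustness to real-data features the generator omits:
negative CD4 changes, measurement error in CD4 counts, visit-time jitter,
non-MCAR dropout beyond the shared-parameter link, or clinic-level
operational structure.

## Inference

One Metropolis-within-Gibbs engine serves the mixed longitudinal fits, the
frailty survival fits, and the joint model:

- **Latent updates.** Visit perturbations, random intercepts/slopes,
  log-dispersions and frailties move by vectorised random-walk Metropolis,
  one accept/reject per observation or patient (valid because patients are
  conditionally independent). Proposal SDs are the product of an adapted
  global scale and a per-unit relative scale proportional to
  1/sqrt(information) (roughly 1/sqrt(count mass involved)), so patients
  with very large counts get correspondingly fine moves.
- **Recentering moves.** Each fixed effect is aliased with a latent
  direction (patient-level covariate with `nu0`, the time slope with
  `nu1`, survival covariates and loadings with the frailty). A joint shift
  along the likelihood-invariant direction is proposed from its exact
  Gaussian conditional; all Gaussian terms then cancel and the acceptance
  ratio reduces to the survival-link ratio (exactly 1 where the hazard is
  also invariant). Without these moves the fixed effects mix at the random
  walk speed of the whole latent field.
- **Slope ridge move.** A per-patient proposal that changes the slope while
  holding the fitted level at that patient's mean observed time fixed — the
  direction the separate intercept/slope walks mix worst along.
- **Variance components.** Conjugate draws: inverse-Wishart for Sigma_nu,
  inverse-gamma for sigma_b^2, sigma_nu^2 and (homogeneous) sigma_eps^2.
  An interweaving move rescales the frailty vector and its variance
  together, breaking the funnel coupling between the two; the frailty block
  is additionally held frozen for the first 40% of burn-in so early misfit
  of the fixed effects is not absorbed into the frailty spread.
- **Shape and scale.** `log rho`, `log phi` move by random walk with
  Gamma(1,1) priors (correct Jacobian); when the survival design contains
  an intercept, `phi` is fixed at 1 (the two are aliased).
- **Initialisation.** Fixed effects start at a Poisson GLM fit — except
  the time coefficient, which starts at the median *within-patient*
  log-count slope: the marginal GLM slope is inflated by survivor
  composition when steep-slope patients stay longest, and a chain started
  there can settle in a self-consistent wrong basin. Random intercepts,
  slopes and perturbations start at residual-based estimates; loadings at a
  Weibull fit on those initial latents (clipped to ±4). Chains are
  jittered.
- **Adaptation** of proposal scales targets 30% acceptance and is frozen
  at the end of burn-in, preserving detailed balance afterwards.

**Priors.** Normal(0, 10^2) on fixed effects; Normal(0, 2.5^2) on the
association loadings (they are soft-identified at desk scale — several
exchangeable latent channels feed `W2` — and a flat prior lets them random
walk over ±20 along likelihood-flat directions); Gamma(1, 1) on `rho` and
`phi`; inverse-gamma(2, 0.2) on scalar variance components (prior mean 0.2,
a weakly informative choice for log-scale heterogeneity variances with a
proper sigma^-6 right tail); inverse-Wishart(df 4, diag(0.1, 0.01)) on
Sigma_nu.

**Numerical details.** The Poisson–log-normal marginal likelihood is
evaluated by *adaptive* Gauss–Hermite quadrature (15–25 nodes): each
observation's integrand is re-centred at its mode (damped Newton; the
integrand is strictly concave) with curvature-matched width. Quadrature
centred at zero fails silently once |log y − eta| is large relative to the
perturbation SD — for count data in the hundreds the error reaches
thousands of log-likelihood units. Verified against brute-force quadrature
to ~1e-11. Linear predictors are capped at |eta| = 30 inside every
likelihood (one consistent capped target); the generator caps |log mu| at
20 with a logged warning.

**Convergence reporting** computes Geweke z (first 10% vs last 50%),
effective sample size and split R-hat per scalar parameter; by default
marginal diagnostics warn (`on_nonconvergence="error"` raises instead).

## Model comparison

DIC is conditional on the patient-level latent effects: the deviance is
−2 × [Poisson–log-normal likelihood marginal over the visit perturbation,
given (nu, b), plus the censored Weibull likelihood given W2]. `Dbar`
averages over (a subsample of) posterior draws; `D_hat` plugs in posterior
means of parameters and latents; `pD = Dbar − D_hat` (reported with a
warning when negative, a known pathology, never hidden). The ladder fits
fixed-effects-only, +random-intercept, and the full
intercept+slope+frailty model and flags the smallest-DIC rung; a failing
rung is marked and the ladder continues.

The count-family comparison pits the mixed Poisson–log-normal fit (MCMC
engine) against the maximum-likelihood negative binomial (variance
mu + alpha mu^2) on AIC, BIC and Pearson chi-square/df, smaller better,
with ties declared and criterion disagreements flagged. For mixed fits the
"log-likelihood" is evaluated at posterior means conditional on the
estimated random effects (a quasi-likelihood stand-in: the quasi-Poisson
family has no likelihood, so information criteria for it are defined
through the Poisson–log-normal), the Pearson statistic uses conditional
means E[y | latents] = exp(eta + b/2) with dof = N − k. Survival criteria
follow the same layout; cells that are undefined for an engine (Pearson
chi-square for the Cox partial likelihood; its BIC is flagged approximate,
computed with the event count as sample size) are reported as unavailable,
not fabricated.

## Missingness diagnostic

The MCAR check fits a maximum-likelihood logistic regression of the
visit-level indicator (1 = not missing, 0 = missing) on age, follow-up
time, sex, residence, marital status and the previous-count rise indicator
(1 if the last two observed counts rose; undefined rows dropped — the
convention for the first change is that no rise status exists until two
prior counts are observed). The verdict is "consistent with MCAR" iff every
non-intercept term is insignificant at alpha after a family-wise correction
(Bonferroni by default; an uncorrected mode mirrors a per-term read-out).
Complete separation falls back to a ridge-penalised likelihood
(lambda = 1e-3) with a logged note. Descriptive percentages are count/total
rounded half-up to one decimal.

## Known limitations

- **The association loadings are weakly identified at cohort scale.** The
  information about `tau1` (the slope loading) comes almost entirely from
  patients who default mid-study with enough visits to measure a slope;
  with slope SD 0.105/visit against visit-level noise of SD ~1, the honest
  posterior SD for `tau1` at n = 792 is ~1.2–1.5. Sign recovery of the
  generating value (−2.324) is therefore unreliable replicate by
  replicate, even though oracle fits with the true latent effects recover
  it decisively. Plug-in regression on estimated (shrunken) slopes is
  *systematically wrong-signed* — a survivor-composition artifact — which
  is precisely why the joint model, not a two-stage analysis, is needed.
- The three rungs of the DIC ladder are compared at reduced chain lengths
  in the test suite; the ladder's per-rung deviances carry Monte-Carlo
  error of order hundreds, small against the between-rung gaps (thousands)
  under the default calibration.
- Discrete follow-up counts are treated as continuous event times in the
  Weibull likelihood; the Cox fit uses Breslow tie handling.
- No competing risks, time-varying covariates, left truncation, GEE,
  zero-inflated families, spline trends, or MNAR generators beyond the
  shared-parameter link itself.

## Problem sizes used by the test suite

Unit and property tests run cohorts of 120–800 patients with single chains
of 600–2000 iterations; the end-to-end checks use n = 792 (shape and
association recovery; association at 2500 iterations × 10 seeds) and
n = 250 × 10 replicates × 3 rungs for the ladder. These sizes were chosen
so the whole suite completes in a few minutes while leaving the Monte-Carlo
error small relative to each assertion's margin.
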