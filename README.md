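# cd4joint

Joint Bayesian modelling of longitudinal CD4 cell-count change and time to
default from HAART (highly active antiretroviral therapy).

HIV cohorts followed under HAART yield two intertwined outcomes per
patient: the repeated per-visit change in CD4 cell count (a noisy,
overdispersed count), and how many follow-up visits the patient attends
before defaulting from treatment. Patients whose CD4 trajectory behaves
badly tend to drop out — so the dropout process is informative, and
analysing either outcome alone is biased. `cd4joint` is for
biostatisticians and epidemiologists who want to fit the two outcomes
jointly, linked through shared patient-level random effects, and to
validate every stage of that analysis on synthetic cohorts with a known
truth.

## The model

Longitudinal submodel (Poisson–log-normal GLMM, log link), for patient *i*
at follow-up visit *j*:

```
log μ_ij = x_ij'β₁ + ν₀ᵢ + ν₁ᵢ t_j + ε_ij,      y_ij | ε_ij ~ Poisson(μ_ij)
ε_ij ~ N(0, bᵢ),   log bᵢ ~ N(0, σ_b²),   (ν₀ᵢ, ν₁ᵢ) ~ N₂(0, Σ_ν)
```

Survival submodel (Weibull proportional hazards on the follow-up-visit
clock, multiplicative frailty):

```
h_i(t) = φ ρ t^(ρ−1) exp( x_i'β₂ + W₂ᵢ )
W₂ᵢ = τ₀ν₀ᵢ + τ₁ν₁ᵢ + τ_b log bᵢ + uᵢ,   uᵢ ~ N(0, σ_ν²)
```

The loadings τ tie the trajectory's level, slope and volatility to the
hazard of defaulting; ρ < 1 means the default rate falls as follow-ups
accumulate. Inference is Metropolis-within-Gibbs MCMC; model selection
walks a nested random-effects ladder (fixed effects only → +random
intercept → +slope+frailty) by DIC. Separate fits (quasi-Poisson-style vs
negative binomial counts; Weibull/exponential vs Cox survival), an MCAR
missingness diagnostic, and a synthetic cohort generator calibrated to a
published Ethiopian HAART cohort (n = 792) round out the toolkit. The
modelling details and all calibration choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

`examples/survival_models.py` simulates a 500-patient cohort and fits the
separate time-to-default models:

```
Weibull shape rho = 0.839 (95% CI 0.740, 0.952)
-> the default rate is decreasing in the number of follow-ups.

hazard ratios (exp of coefficients):
                   hr  hr_lower  hr_upper
age             0.960     0.948     0.971
female          1.157     0.880     1.521
adherence_poor  0.657     0.411     1.048
adherence_fair  0.618     0.424     0.900

                weibull     cox   winner
aic              1851.7  2437.0  weibull
bic              1876.9  2450.4  weibull
```

The shape estimate below one says the hazard of defaulting declines the
longer a patient stays in follow-up; each year of age multiplies the
hazard by 0.96; the parametric Weibull model beats the Cox fit on both
information criteria, so the parametric baseline is adequate for these
data. The other scripts in `examples/` walk the remaining capabilities:
cohort simulation and descriptives, the overdispersion check and
count-family choice, the joint fit with its DIC ladder and hazard-ratio
table, and the MCAR diagnostic.

A minimal joint fit from Python:

```python
import cd4joint as cj

cohort = cj.simulate_cohort(n=250, seed=9)
spec = cj.JointModelSpec(
    longitudinal_terms=["intercept", "age", "female", "time"],
    survival_terms=["intercept", "age", "female"],
)
result = cj.run_mcmc(cohort.longitudinal, cohort.survival, cohort.covariates,
                     spec, cj.McmcSettings(chains=2, seed=1))
print(result.summaries)          # posterior means, SDs, credible intervals
print(result.dic)                # (Dbar, D_hat, pD, DIC)
print(cj.hazard_ratio_table(result))
```

A thin command-line wrapper (`cd4joint simulate | fit-longitudinal |
fit-survival | fit-joint | mcar-check | report`) covers the same pipeline
for shell use; `--help` on any subcommand shows its options.

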