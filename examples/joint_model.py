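"""Fit the shared-parameter joint model and walk the DIC ladder.

The longitudinal Poisson-log-normal GLMM and the Weibull survival submodel
share the patient's random intercept and slope, the log-dispersion, and a
frailty through the latent term W2 in the log hazard.  The random-effects
ladder refits the model with (i) fixed effects only, (ii) a random
intercept, (iii) intercept + slope + frailty with the shared loadings, and
ranks the rungs by DIC (smaller is better).
"""

import cd4joint as cj

cohort = cj.simulate_cohort(n=250, seed=9)
lt = ["intercept", "age", "female", "adherence_poor", "adherence_fair", "time"]
st = ["intercept", "age", "female", "adherence_poor", "adherence_fair"]
settings = cj.McmcSettings(chains=1, iterations=2000, burn=1000, thin=2, seed=10,
                           adapt_interval=25)

ladder = cj.run_ladder(cohort.longitudinal, cohort.survival, cohort.covariates,
                       lt, st, settings)
print(ladder[["ladder_level", "dic", "p_d", "selected"]].round(1).to_string(index=False))
print("\nDIC falls as the shared random effects enter; the selected rung has")
print("the smallest DIC, mirroring the model-selection ladder of the analysis.\n")

result = ladder.attrs["results"]["intercept_slope_frailty"]
print(result.summaries.round(3).to_string())
print("\nhazard ratios (posterior mean and 95% credible interval):")
print(cj.hazard_ratio_table(result).round(3).to_string())
print(
    "\ntau0/tau1 load the random intercept/slope into the hazard; a negative"
    "\ntau1 means patients whose CD4 change rises faster default later."
)
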