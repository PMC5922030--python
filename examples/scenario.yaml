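# Example scenario for the CLI: `cd4joint simulate --config examples/scenario.yaml --out scratch/cohort`
n: 792
seed: 1
max_followups: 20
miss_prob: 0.1
# restrict the preset fixed effects to a desk-scale covariate set
terms: [age, female, adherence_poor, adherence_fair]
params:
  rho: 0.864          # Weibull shape: <1 means a falling default rate
  sigma_b2: 0.25      # variance of the patient log-dispersion
sampler:
  chains: 2
  iterations: 4000
  burn: 2000
  thin: 2
  seed: 1
  adapt_interval: 25
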