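# Full experiment configuration for `evamp run --config examples/config.yaml`.
# Every field is optional; omitted fields fall back to these same defaults.
# Unknown fields are rejected.

# structural parameters of the data-generating process
beta_T: 0.2          # treatment effect on the cure log-odds (and weight on V)
alpha: 1.0           # confounder weight in the treatment utility
beta_m: 0.4          # cure-model coefficient on the observed confounder
beta_u1: 0.4         # ... on the unobserved confounder of both T and C
beta_u2: 0.4         # ... on the indirectly-correlated outcome covariate
V: 1.0               # value of being cured (scalar, same for all patients)
s_family: uniform    # per-patient treatment-cost distribution S
s_low: 1.7
s_high: 2.7
intercept_C: 0.0     # cure-model intercept
n_obs: 10000         # patients per cohort

# experiment layout
rho_grid: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
n_replicates: 200
master_seed: 0
calipers: [0.001, 0.01, 0.1]
# methods: [all_confounders]   # optionally restrict the estimator set
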