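# evamp — the E-value under bias amplification

`evamp` is a Monte Carlo simulation framework for a question that matters to
anyone who reports an E-value after a propensity-score analysis: **what does
the E-value actually tell you when the adjustment itself has amplified the
bias from unobserved confounding?**

The E-value (VanderWeele & Ding) is the minimum strength of association, on
the risk-ratio scale, that an unmeasured confounder would need with both
treatment and outcome to fully explain away an observed association:

```
E = RR* + sqrt(RR* · (RR* − 1)),   RR* = max(RR, 1/RR)
```

Propensity-score matching (PSM) and inverse-probability-of-treatment
weighting (IPTW) balance *observed* covariates, but balancing observables can
*increase* imbalance in unobserved covariates that drive treatment choice —
bias amplification.  `evamp` generates cohorts in which the strength of that
mechanism is a single dial, runs the standard estimator toolbox on each
cohort, and tracks what happens to covariate balance, effect estimates, and
E-values.

## The data-generating process

Each simulated patient has an observed confounder `X_m ~ U[0,1]` and four
unobserved covariates tied to it through a correlation weight `ρ ∈ [0, 1)`:

```
X_ui = ρ·X_m + (1−ρ)·μ_i        (i = 1, 3, 4; independent μ_i ~ U[0,1])
X_u2 = 0.5·X_u3 + 0.5·μ
```

Treatment follows a latent net-utility rule with value-of-cure `V`,
per-patient treatment cost `S`, and confounder weight `α`:

```
Tx = V·β_T − S + α·(X_m + X_u1 + X_u3 + X_u4),     T = 1  iff  Tx > 0
```

and the binary cure outcome is logistic:

```
Pr(C = 1) = expit(β_T·T + β_m·X_m + β_u1·X_u1 + β_u2·X_u2)
```

`β_T = 0.2` is the parameter of interest.  Note the structure: `X_u3`/`X_u4`
affect treatment only (near-instruments once ρ > 0), `X_u2` affects the
outcome only but is correlated with `X_u3`, and `X_u1` affects both.

Five estimation strategies are fit to every cohort: logistic regressions of
`C` on `T` with (1) no confounders, (2) `X_m` only, (3) the full information
set `{X_m, X_u1, X_u2}`; (4) IPTW with unstabilized ATE weights from a probit
propensity model on `X_m`; and (5) 1:1 greedy caliper matching on the same
score (calipers 0.001, 0.01, 0.1).  Each fitted model is converted to a
marginal risk ratio by g-computation (standardization over the analytic
sample), and each risk ratio to an E-value.

## Worked example

```python
from evamp import MCConfig, run_monte_carlo

config = MCConfig(n_replicates=50, rho_grid=(0.0, 0.9), master_seed=0)
summary, replicates = run_monte_carlo(config)
cols = ["rho", "method", "caliper", "beta_T_hat_median", "rr_median",
        "evalue_median", "common_support_median"]
print(summary[cols].round(3).to_string(index=False))
```

```
 rho              method  caliper  beta_T_hat_median  rr_median  evalue_median  common_support_median
 0.0     all_confounders      NaN              0.189      1.064          1.324                    NaN
 0.0                iptw      NaN              0.333      1.117          1.478                  0.999
 0.0      no_confounders      NaN              0.401      1.142          1.546                    NaN
 0.0 observed_confounder      NaN              0.342      1.118          1.482                    NaN
 0.0                 psm    0.001              0.331      1.116          1.475                  0.673
 0.0                 psm    0.010              0.342      1.120          1.486                  0.693
 0.0                 psm    0.100              0.370      1.130          1.512                  0.837
 0.9     all_confounders      NaN              0.183      1.062          1.318                    NaN
 0.9                iptw      NaN              0.496      1.182          1.647                  0.283
 0.9      no_confounders      NaN              0.636      1.238          1.782                    NaN
 0.9 observed_confounder      NaN              0.185      1.063          1.321                    NaN
 0.9                 psm    0.001              0.180      1.059          1.309                  0.113
 0.9                 psm    0.010              0.200      1.068          1.337                  0.136
 0.9                 psm    0.100              0.194      1.067          1.336                  0.155
```

Reading this: the correctly specified regression (`all_confounders`) recovers
β_T ≈ 0.2 at both correlation levels.  The naive regression is biased upward
(0.40) and gets worse as ρ grows (0.64).  At ρ = 0 the PS methods behave like
the observed-confounder regression; at ρ = 0.9, IPTW drifts toward the naive
estimate (0.50) while its common support collapses (0.28), and tight-caliper
PSM stays near the truth but retains only 11% of the cohort.  The E-value
median moves with the bias: the most biased cells report the *largest*
E-values, i.e. the most misplaced confidence that unmeasured confounding
cannot explain the result.

The same experiment is available from a shell:

```bash
evamp run --out results/ --replicates 200 --seed 0          # full grid sweep
evamp report --in results/                                   # tables + figures
evamp evalue --rr 1.07                                       # prints 1.34374
```

`evamp run` writes `table1.csv` (per-ρ medians and SDs per method),
`summary_long.csv` (tidy metrics), `replicates.csv` (per-fit log) and a
`config.yaml` provenance echo.

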