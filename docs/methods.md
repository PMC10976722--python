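# Methods

## The model

A cohort of `n` patients chooses a binary treatment by a latent-utility
threshold and experiences a binary cure outcome from a logistic model.
Covariates are all bounded in [0, 1] by construction (each is a convex
combination of uniform draws):

* `X_m ~ U[0, 1]` — the confounder the analyst observes;
* `X_ui = ρ·X_m + (1−ρ)·μ_i` for `i ∈ {1, 3, 4}`, each with its own fresh
  `μ_i ~ U[0, 1]` per patient.  The implied correlation with `X_m` is
  `ρ/√(ρ² + (1−ρ)²)` (0 at ρ=0, 0.707 at ρ=0.5, →1 as ρ→1);
* `X_u2 = 0.5·X_u3 + 0.5·μ` with another independent draw, so `X_u2`
  touches treatment only through its correlation with `X_u3`.

A single symbol could be read as one shared mixing draw across
`X_u1, X_u3, X_u4`; that reading makes the three covariates identical and
the model degenerate, so each covariate gets an independent draw.

Treatment: `Tx = V·β_T − S + α·(X_m + X_u1 + X_u3 + X_u4)`, `T = 1` iff
`Tx > 0` strictly — a patient exactly indifferent stays untreated.
Outcome: `Pr(C=1) = expit(c + β_T·T + β_m·X_m + β_u1·X_u1 + β_u2·X_u2)`
with intercept `c = 0` by default (exposed as `intercept_C` for
calibration experiments only).

The structural asymmetry is the point of the design: `X_u3`/`X_u4` are
treatment-only covariates (near-instruments once ρ > 0), `X_u1` is a
classical unobserved confounder, and `X_u2` is an outcome covariate
reached indirectly through `X_u3`.  Balancing `X_m` can therefore
*increase* imbalance in `X_u1`, which is the bias-amplification channel
under study.

## Calibrated defaults

`β_T = 0.2`, the cohort size (10,000) and the ρ grid (0 to 0.9 by 0.1)
are fixed design constants of the study.  The remaining structural
parameters have no canonical published values, so the package ships one
calibrated default set, chosen once by a coarse scout search (small
replicate counts) against three requirements and then frozen:

| parameter | default | role / why |
|---|---|---|
| `α` | 1.0 | weight of every confounder in the treatment utility |
| `β_m, β_u1, β_u2` | 0.4 | puts the marginal cure prevalence near 0.645, the level at which a log-odds effect of 0.2 standardizes to a risk ratio of ≈ 1.07 |
| `V` | 1.0 | scalar value of cure; only the product `V·β_T` matters |
| `S` | Uniform[1.7, 2.7] | per-patient treatment cost.  Centring at `E[V·β_T + α·ΣX] = 2.2` makes the treated fraction exactly 1/2 at every ρ by symmetry.  The width (1.0) is the load-bearing choice: it sets how deterministic treatment is in `X_m` at high ρ |

The `S` width deserves a note.  With a very wide cost distribution,
`Pr(T=1|X_m)` stays gentle at every ρ, the probit/IPTW adjustment works
almost perfectly, and IPTW bias *decreases* with ρ — the bias-amplification
regime never appears.  A width of 1.0 makes treatment nearly deterministic
in `X_m` as ρ → 0.9: propensity scores spread to the extremes, weights
explode, common support collapses, and IPTW drifts toward the unadjusted
estimate, which is the regime the study is about.  All of these parameters
are plain config fields (`MCConfig` / `DGPParams`), nothing is hard-coded
in the operations.

## Estimators

* Outcome regressions: ML logistic fits (statsmodels GLM, binomial/logit)
  of `C` on `T` plus no covariates, `{X_m}`, or `{X_m, X_u1, X_u2}`.
  `X_u3`, `X_u4` never enter an outcome model — they have no direct
  outcome effect and conditioning on near-instruments is exactly what the
  design avoids in the "full information" benchmark.
* Propensity scores: probit of `T` on `X_m`; fitted probabilities clipped
  to `[1e-12, 1 − 1e-12]` (the probit CDF underflows to exact 0/1 under
  near-separation, which otherwise breaks weighting).
* IPTW: unstabilized ATE weights `1/ps` (treated), `1/(1−ps)` (controls),
  applied to a weighted logistic fit of `C` on `T` alone — the weights
  carry the whole adjustment, mirroring how PS methods are contrasted
  with covariate regression.  Stabilized weights exist behind a flag,
  default off; no truncation.
* PSM: 1:1 greedy nearest-neighbour caliper matching without replacement
  on the probit score.  Processing order is pinned because "greedy" alone
  underdetermines the output: treated units in descending score
  (ascending index on ties); nearest unused control within the caliper,
  distance ties to the smaller control index; unmatched treated dropped.
  The implementation keeps controls in a sorted array with union-find
  "nearest alive neighbour" pointers (near-linear overall); tests pit it
  against a quadratic brute-force enumeration of the same rule, including
  tie configurations.  The outcome model within the matched sample is an
  unadjusted logistic fit of `C` on `T` — the standard marginal-effect
  choice for 1:1 matched binary outcomes; no pair strata, no covariates.
* Failure policy: degenerate outcomes, separation, or non-convergence
  yield a flagged not-converged `FitResult`; aggregation counts and
  excludes them (`n_failed`) and never aborts a sweep.

## Diagnostics

* SMD: `|mean_T − mean_C| / √((s²_T + s²_C)/2)`, computed on the sample
  under analysis — frequency-weighted moments for IPTW (identical to
  expanding integer weights), the matched subset for PSM.  Standardizing
  by pre-adjustment SDs is available behind a flag.  Reported as a
  magnitude by default.
* Common support: the closed overlap interval of the two arms' score
  ranges `[max of minima, min of maxima]`; the statistic is the fraction
  of *all* patients inside it, ties included.
* For PSM summary rows, the "common support" column instead reports
  matched-sample retention (`2·pairs/n`).  With one shared propensity
  model the range-overlap statistic cannot distinguish weighting from
  matching, while retention is the quantity that actually shrinks the
  PSM analytic sample as ρ grows — and it reproduces the expected
  ordering (PSM below IPTW at every ρ > 0).
* Bias: `β_T − β̂_T`, true minus estimate, so upward bias is negative.
  Kept in that orientation because the bias/E-value summaries only use
  magnitudes and ranks.

## Risk ratios and E-values

A logistic `β̂_T` is a conditional log odds ratio; the outcome is common
(≈ 0.65 cured), so the odds ratio overstates the risk ratio badly, and the
RR is obtained by standardization: predict every analytic-sample patient's
cure probability with `T` forced to 1 and to 0, average each arm (with
IPTW weights / over the matched subset, following the fit), and take the
ratio.  Both OR and standardized RR are kept side by side in the output.
A conditional-at-covariate-means RR is available behind a flag but never
used in the summaries; in the rare-outcome limit the standardized RR
converges to the OR (covered by a test).

E-value: `E = RR* + √(RR*·(RR*−1))` with `RR* = max(RR, 1/RR)`, so
`E(RR) = E(1/RR)` exactly and `E = 1` iff `RR = 1`.  A sign-flipped
variant of the radicand sometimes seen in print, `RR·(1−RR)`, is negative
for `RR > 1` and is not implemented.  Point-estimate E-values only; no
confidence-limit E-values, no non-null thresholds.

## The Monte Carlo driver

Each `(ρ, replicate)` cell derives its own integer seed from the master
seed via `SeedSequence(master, spawn_key=(1000ρ, replicate))`, so
enlarging the grid or the replicate count never perturbs existing
streams, and a sweep is bit-reproducible from `(config, master_seed)`.
Aggregation reports medians, across-replicate SDs, and 5th/95th
percentiles per `(ρ, method, caliper)`; medians are the primary summary.
Outputs are plain CSVs plus a `config.yaml` provenance echo; figure
generation (balance, support, estimates, bias-vs-E-value) is optional
and degrades cleanly when matplotlib is absent.

## Problem sizes

The package's standard profile is 200 replicates of 10,000-patient
cohorts over the ten-point ρ grid — about three minutes for all five
estimators on one CPU, and what the test suite and acceptance script
run.  A 1,000-replicate profile sits behind `evamp run --full`; it
changes Monte Carlo noise (the SE of a median scales as `n_rep^-1/2`),
not any qualitative conclusion.  Unit tests that check distributional
identities use cohorts of 10^5–10^6 as noted per test.

## What the generator does and does not emulate

The generator produces exactly the stylized world the study needs:
uniform bounded covariates, one dial (ρ) for observed–unobserved
correlation, homogeneous treatment effect, no missingness, no
measurement error, and a single observed confounder so the propensity
model is trivially correctly specified.  Passing tests therefore show
how E-values behave *under bias amplification*, not that any particular
real dataset suffers it: with richer covariates, non-uniform
distributions, or treatment-effect heterogeneity the magnitudes (though
not the mechanism) can differ.  Results also do not generalize to data
without independent variation in the unobserved treatment-only
covariates — with ρ fixed at 1 the model would collapse.

## Known limitations

* Only two PS methods (1:1 greedy caliper matching, unstabilized IPTW);
  no optimal/full matching, no doubly-robust or covariate-balancing
  estimators, no bootstrap inference.
* Model-based SEs per fit; the summaries use across-replicate SDs, so
  per-fit SEs are informational only (a sandwich option exists).
* The matcher's pinned processing order is one of several defensible
  "greedy" conventions; alternatives would change pairings, not the
  qualitative results.
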