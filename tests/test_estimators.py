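"""Outcome regressions, the probit propensity model, IPTW weights, and matching."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from conftest import cohort_from_arrays, greedy_match_bruteforce
from evamp.dgp import DGPParams, simulate_cohort
from evamp.estimators import (
    compute_iptw_weights,
    estimate_all_methods,
    fit_logistic,
    fit_probit_propensity,
    greedy_match,
)


def two_by_two_cohort():
    # counts: (T=1,C=1)=30, (1,0)=10, (0,1)=20, (0,0)=20
    T = np.repeat([1, 1, 0, 0], [30, 10, 20, 20])
    C = np.repeat([1, 0, 1, 0], [30, 10, 20, 20])
    return cohort_from_arrays(T, C)


class TestFitLogistic:
    def test_saturated_two_by_two_equals_log_odds_ratio(self):
        fit = fit_logistic(two_by_two_cohort())
        assert fit.converged
        expected = np.log((30 * 20) / (10 * 20))  # ln 3
        assert fit.beta_T_hat == pytest.approx(expected, abs=1e-8)
        assert fit.odds_ratio == pytest.approx(np.exp(fit.beta_T_hat))
        assert fit.n_analytic == 80

    def test_degenerate_outcome_flagged_not_converged(self):
        cohort = cohort_from_arrays(T=[0, 1, 0, 1], C=[1, 1, 1, 1])
        fit = fit_logistic(cohort)
        assert not fit.converged
        assert np.isnan(fit.beta_T_hat)

    def test_mle_recovers_true_effect_at_large_n(self):
        cohort = simulate_cohort(DGPParams(rho=0.3, seed=8, n_obs=100_000))
        fit = fit_logistic(cohort, ("X_m", "X_u1", "X_u2"))
        assert fit.converged
        assert abs(fit.beta_T_hat - 0.2) < 3 * fit.se_beta_T

    def test_robust_se_differs_but_coefficient_identical(self, default_cohort):
        plain = fit_logistic(default_cohort, ("X_m",))
        robust = fit_logistic(default_cohort, ("X_m",), robust_se=True)
        assert robust.beta_T_hat == pytest.approx(plain.beta_T_hat)
        assert robust.se_beta_T != plain.se_beta_T

    def test_weights_change_the_fit(self, default_cohort):
        plain = fit_logistic(default_cohort)
        rng = np.random.default_rng(0)
        w = rng.uniform(0.5, 2.0, default_cohort.n)
        weighted = fit_logistic(default_cohort, weights=w)
        assert weighted.converged
        assert weighted.beta_T_hat != plain.beta_T_hat


class TestProbitPropensity:
    def test_treatment_independent_of_xm(self):
        rng = np.random.default_rng(3)
        n = 20_000
        T = (rng.uniform(size=n) < 0.4).astype(int)
        cohort = cohort_from_arrays(T, C=rng.integers(0, 2, n), X_m=rng.uniform(size=n))
        ps = fit_probit_propensity(cohort)
        assert np.all((ps > 0) & (ps < 1))
        assert np.abs(ps - T.mean()).max() < 0.03  # flat in X_m

    def test_scores_monotone_in_xm(self, default_cohort):
        ps = fit_probit_propensity(default_cohort)
        order = np.argsort(default_cohort.X_m)
        assert np.all(np.diff(ps[order]) >= 0)

    def test_matches_independent_optimizer(self):
        rng = np.random.default_rng(12)
        n = 200
        x = rng.uniform(size=n)
        T = (rng.uniform(size=n) < norm.cdf(-0.3 + 1.2 * x)).astype(int)
        cohort = cohort_from_arrays(T, C=rng.integers(0, 2, n), X_m=x)
        ps = fit_probit_propensity(cohort)

        def negll(beta):
            eta = beta[0] + beta[1] * x
            p = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
            return -(T * np.log(p) + (1 - T) * np.log(1 - p)).sum()

        res = minimize(negll, x0=[0.0, 0.0], method="BFGS")
        oracle_ps = norm.cdf(res.x[0] + res.x[1] * x)
        assert np.abs(ps - oracle_ps).max() < 1e-6

    def test_single_arm_rejected(self):
        cohort = cohort_from_arrays(T=[1, 1, 1], C=[0, 1, 0], X_m=[0.1, 0.5, 0.9])
        with pytest.raises(ValueError):
            fit_probit_propensity(cohort)


class TestIPTWWeights:
    def test_direct_formula(self):
        ps = np.array([0.5, 0.25, 0.25])
        T = np.array([1, 1, 0])
        w = compute_iptw_weights(ps, T)
        assert w == pytest.approx([2.0, 4.0, 4.0 / 3.0])

    def test_uniform_half_scores(self):
        w = compute_iptw_weights(np.full(10, 0.5), np.arange(10) % 2)
        assert np.all(w == 2.0)

    def test_boundary_scores_rejected(self):
        with pytest.raises(ValueError):
            compute_iptw_weights(np.array([0.0, 0.5]), np.array([0, 1]))
        with pytest.raises(ValueError):
            compute_iptw_weights(np.array([1.0, 0.5]), np.array([0, 1]))

    def test_stabilized_weights_scale_by_arm_probability(self):
        ps = np.array([0.25, 0.25, 0.5, 0.5])
        T = np.array([1, 0, 1, 0])
        w = compute_iptw_weights(ps, T, stabilized=True)
        plain = compute_iptw_weights(ps, T)
        expected = plain * np.where(T == 1, 0.5, 0.5)
        assert w == pytest.approx(expected)

    def test_horvitz_thompson_weight_total(self):
        # under a correct PS model the weights sum to about 2n
        rng = np.random.default_rng(21)
        n = 100_000
        ps = rng.uniform(0.2, 0.8, n)
        T = (rng.uniform(size=n) < ps).astype(int)
        w = compute_iptw_weights(ps, T)
        assert abs(w.sum() / (2 * n) - 1.0) < 0.02


class TestGreedyMatch:
    def test_spec_worked_example(self):
        ps = np.array([0.31, 0.30, 0.295, 0.32])
        T = np.array([1, 1, 0, 0])
        pairs = greedy_match(ps, T, caliper=0.02)
        # 0.31 processed first, matched to 0.32 (d=0.01 beats 0.015);
        # 0.30 then matched to 0.295
        assert pairs.tolist() == [[0, 3], [1, 2]]

    def test_no_control_within_caliper(self):
        ps = np.array([0.9, 0.1])
        T = np.array([1, 0])
        assert greedy_match(ps, T, caliper=0.05).size == 0

    def test_empty_arms_give_empty_pairs(self):
        assert greedy_match(np.array([0.4, 0.5]), np.array([1, 1]), 0.1).size == 0

    def test_invalid_caliper(self):
        with pytest.raises(ValueError):
            greedy_match(np.array([0.4, 0.5]), np.array([1, 0]), 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_constraints_hold_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 500
        ps = rng.uniform(size=n)
        T = (rng.uniform(size=n) < 0.5).astype(int)
        caliper = 0.02
        pairs = greedy_match(ps, T, caliper)
        controls = pairs[:, 1]
        assert len(np.unique(controls)) == len(controls)  # without replacement
        assert np.all(np.abs(ps[pairs[:, 0]] - ps[pairs[:, 1]]) <= caliper)
        assert np.all(T[pairs[:, 0]] == 1) and np.all(T[pairs[:, 1]] == 0)

    def test_agrees_with_bruteforce_including_ties(self):
        rng = np.random.default_rng(99)
        for i in range(100):
            n = int(rng.integers(2, 30))
            # coarse grid ps to provoke exact ties
            ps = rng.integers(0, 8, n) / 8.0
            T = (rng.uniform(size=n) < 0.5).astype(int)
            caliper = float(rng.choice([0.13, 0.26, 1.0]))
            got = [tuple(p) for p in greedy_match(ps, T, caliper)]
            assert got == greedy_match_bruteforce(ps, T, caliper), (i, ps, T, caliper)

    def test_saturated_ps_equals_exact_matching(self):
        # with a two-valued score, greedy matching within a tight caliper
        # is exact matching: per level, min(#treated, #controls) pairs
        rng = np.random.default_rng(4)
        n = 400
        level = rng.integers(0, 2, n)
        ps = np.where(level == 1, 0.7, 0.3)
        T = (rng.uniform(size=n) < 0.5).astype(int)
        pairs = greedy_match(ps, T, caliper=0.001)
        for val in (0.3, 0.7):
            n_t = int(((ps == val) & (T == 1)).sum())
            n_c = int(((ps == val) & (T == 0)).sum())
            got = int((ps[pairs[:, 0]] == val).sum())
            assert got == min(n_t, n_c)
            assert np.all(ps[pairs[:, 0]] == ps[pairs[:, 1]])


class TestEstimateAllMethods:
    def test_seven_fit_results_and_covariate_sets(self, default_cohort):
        fits, artifacts = estimate_all_methods(default_cohort)
        assert len(fits) == 7
        by_method = {}
        for f in fits:
            by_method.setdefault(f.method, []).append(f)
        assert set(by_method) == {
            "no_confounders",
            "observed_confounder",
            "all_confounders",
            "iptw",
            "psm",
        }
        assert by_method["all_confounders"][0].covariate_set == ("X_m", "X_u1", "X_u2")
        # the treatment-only instruments never enter an outcome model
        for f in fits:
            assert "X_u3" not in f.covariate_set and "X_u4" not in f.covariate_set
        assert sorted(f.caliper for f in by_method["psm"]) == [0.001, 0.01, 0.1]
        for f in by_method["psm"]:
            assert f.n_analytic % 2 == 0  # 1:1 pairs

    def test_deterministic_given_cohort(self, default_cohort):
        fits_a, _ = estimate_all_methods(default_cohort)
        fits_b, _ = estimate_all_methods(default_cohort)
        for a, b in zip(fits_a, fits_b):
            assert a.beta_T_hat == b.beta_T_hat and a.n_analytic == b.n_analytic

    def test_matched_pairs_respect_artifact_invariants(self, default_cohort):
        _, artifacts = estimate_all_methods(default_cohort)
        for key, art in artifacts.items():
            if not key.startswith("psm"):
                continue
            ps = art.propensity_scores
            pairs = art.matched_pairs
            assert np.all(np.abs(ps[pairs[:, 0]] - ps[pairs[:, 1]]) <= art.caliper)
            assert len(np.unique(pairs[:, 1])) == len(pairs)
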