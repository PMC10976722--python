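"""Treatment-effect estimators: outcome regressions, IPTW, and greedy PS matching.

Five strategies are contrasted on each cohort:

* ``no_confounders``     — logistic regression of C on T alone
* ``observed_confounder``— logistic regression of C on T and X_m
* ``all_confounders``    — logistic regression of C on T, X_m, X_u1, X_u2
  (the covariates that actually enter the outcome model; the
  treatment-only instruments X_u3, X_u4 never enter any outcome fit)
* ``iptw``               — logistic regression of C on T weighted by
  unstabilized inverse-probability-of-treatment (ATE) weights from a
  probit propensity model with X_m as the only control
* ``psm``                — 1:1 greedy caliper matching on the same probit
  propensity score, then an unadjusted logistic regression of C on T
  within the matched sample
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .dgp import Cohort

__all__ = [
    "FitResult",
    "AdjustmentArtifact",
    "fit_logistic",
    "fit_probit_propensity",
    "compute_iptw_weights",
    "greedy_match",
    "estimate_all_methods",
    "METHODS",
]

METHODS = ("no_confounders", "observed_confounder", "all_confounders", "iptw", "psm")

#: covariate sets for the three outcome-regression specifications
REGRESSION_COVARIATES = {
    "no_confounders": (),
    "observed_confounder": ("X_m",),
    "all_confounders": ("X_m", "X_u1", "X_u2"),
}


@dataclass
class FitResult:
    """Output of one estimation method on one cohort."""

    method: str
    beta_T_hat: float
    se_beta_T: float
    odds_ratio: float
    n_analytic: int
    converged: bool
    risk_ratio: float = np.nan  # filled in by the sensitivity module
    caliper: Optional[float] = None
    #: full coefficient vector (name -> value), used for g-computation
    coef: Mapping[str, float] = field(default_factory=dict)
    covariate_set: Sequence[str] = ()


@dataclass
class AdjustmentArtifact:
    """Propensity scores plus the weights or matched pairs derived from them."""

    propensity_scores: np.ndarray
    weights: Optional[np.ndarray] = None
    matched_pairs: Optional[np.ndarray] = None  # shape (k, 2): (treated, control)
    caliper: Optional[float] = None
    common_support_prop: float = np.nan

    def matched_indices(self) -> np.ndarray:
        """Flat indices of all patients in the matched sample."""
        if self.matched_pairs is None or len(self.matched_pairs) == 0:
            return np.empty(0, dtype=np.intp)
        return np.asarray(self.matched_pairs, dtype=np.intp).ravel()


def _failed_fit(method: str, n: int, caliper: Optional[float] = None) -> FitResult:
    return FitResult(
        method=method,
        beta_T_hat=np.nan,
        se_beta_T=np.nan,
        odds_ratio=np.nan,
        n_analytic=n,
        converged=False,
        caliper=caliper,
    )


def fit_logistic(
    cohort: Cohort,
    covariate_set: Sequence[str] = (),
    weights: Optional[np.ndarray] = None,
    subset: Optional[np.ndarray] = None,
    method: str = "logistic",
    caliper: Optional[float] = None,
    robust_se: bool = False,
) -> FitResult:
    """ML logistic regression of C on T plus ``covariate_set`` (intercept included).

    ``weights`` (if given) enter the weighted log-likelihood; ``subset``
    restricts the fit to a row subset (used for matched samples);
    ``robust_se`` swaps the model-based standard errors for HC1 sandwich
    ones.  Separation or non-convergence yields a flagged, not-converged
    result rather than an exception, so a single pathological replicate
    cannot abort a Monte Carlo sweep.
    """
    C = cohort.C
    T = cohort.T
    cols = {"T": T}
    for name in covariate_set:
        cols[name] = cohort.column(name)
    X = np.column_stack([np.ones(cohort.n), *cols.values()])
    names = ["const", *cols.keys()]
    y = np.asarray(C, dtype=float)
    if subset is not None:
        X, y = X[subset], y[subset]
        if weights is not None:
            weights = np.asarray(weights)[subset]
    n_analytic = int(y.shape[0])
    if n_analytic == 0 or y.min() == y.max():
        return _failed_fit(method, n_analytic, caliper)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=weights)
            res = model.fit(maxiter=100, cov_type="HC1" if robust_se else "nonrobust")
        converged = bool(res.converged)
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        return _failed_fit(method, n_analytic, caliper)
    params = dict(zip(names, np.asarray(res.params, dtype=float)))
    beta = params["T"]
    se = float(res.bse[names.index("T")])
    if not np.isfinite(beta) or not np.isfinite(se) or not converged:
        return _failed_fit(method, n_analytic, caliper)
    return FitResult(
        method=method,
        beta_T_hat=float(beta),
        se_beta_T=se,
        odds_ratio=float(np.exp(beta)),
        n_analytic=n_analytic,
        converged=True,
        caliper=caliper,
        coef=params,
        covariate_set=tuple(covariate_set),
    )


def fit_probit_propensity(cohort: Cohort) -> np.ndarray:
    """Probit model of T on X_m; returns fitted Pr(T=1 | X_m), strictly in (0, 1)."""
    T = np.asarray(cohort.T, dtype=float)
    if T.min() == T.max():
        raise ValueError("propensity model requires both treated and untreated patients")
    X = sm.add_constant(np.asarray(cohort.X_m, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Probit(T, X).fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", True):
        raise ValueError("probit propensity model failed to converge (separation?)")
    ps = np.asarray(res.predict(X), dtype=float)
    # probit cdf can round to exactly 0/1 in float; clip to an open interval
    # wide enough to survive 1 - eps rounding
    eps = 1e-12
    return np.clip(ps, eps, 1.0 - eps)


def compute_iptw_weights(
    propensity_scores: np.ndarray, T: np.ndarray, stabilized: bool = False
) -> np.ndarray:
    """Unstabilized ATE weights: 1/ps for treated, 1/(1-ps) for controls.

    ``stabilized=True`` multiplies by the marginal arm probabilities.
    """
    ps = np.asarray(propensity_scores, dtype=float)
    if np.any(ps <= 0.0) or np.any(ps >= 1.0):
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    T = np.asarray(T)
    w = np.where(T == 1, 1.0 / ps, 1.0 / (1.0 - ps))
    if stabilized:
        p_treat = T.mean()
        w *= np.where(T == 1, p_treat, 1.0 - p_treat)
    return w


def greedy_match(
    propensity_scores: np.ndarray, T: np.ndarray, caliper: float
) -> np.ndarray:
    """1:1 greedy nearest-neighbour caliper matching without replacement.

    Treated units are processed in descending propensity-score order
    (ties broken by ascending original index).  Each treated unit takes
    the nearest not-yet-used control with |Δps| ≤ caliper; ties in
    distance go to the control with the smaller original index.
    Unmatched treated units are dropped.  Returns an array of
    (treated_index, control_index) pairs in processing order.
    """
    if caliper <= 0:
        raise ValueError(f"caliper must be > 0; got {caliper}")
    ps = np.asarray(propensity_scores, dtype=float)
    T = np.asarray(T)
    treated = np.flatnonzero(T == 1)
    controls = np.flatnonzero(T != 1)
    if treated.size == 0 or controls.size == 0:
        return np.empty((0, 2), dtype=np.intp)

    # stable sort on (-ps, index): descending ps, ascending index on ties
    t_order = treated[np.argsort(-ps[treated], kind="stable")]

    # controls sorted by (ps, index); the stable sort keeps index order on
    # ties, so at equal distance the neighbour scans below see smaller
    # original indices first on the left side and we compare explicitly
    # on the right side
    c_order = controls[np.argsort(ps[controls], kind="stable")]
    c_ps = ps[c_order]
    m = c_order.size

    # union-find style "nearest alive neighbour" pointers with path
    # compression; nxt[i] = first alive sorted position >= i (m = none),
    # prv[i+1]-1 = last alive sorted position <= i (-1 = none)
    nxt = list(range(m + 1))
    prv = list(range(m + 1))

    def find_right(i: int) -> int:
        path = []
        while nxt[i] != i:
            path.append(i)
            i = nxt[i]
        for p in path:
            nxt[p] = i
        return i

    def find_left(i: int) -> int:  # i in [0, m]; returns alive pos + 1, 0 = none
        path = []
        while prv[i] != i:
            path.append(i)
            i = prv[i]
        for p in path:
            prv[p] = i
        return i

    def kill(i: int) -> None:
        nxt[i] = i + 1
        prv[i + 1] = i

    pairs = []
    for t in t_order:
        pt = ps[t]
        j = int(np.searchsorted(c_ps, pt))
        r = find_right(j) if j < m else m
        l = find_left(j) - 1  # last alive position < j... see below
        # find_left(j) gives largest alive+1 <= j, i.e. alive positions < j;
        # but an alive control AT position >= j with ps == pt is found via r
        best = -1
        best_d = np.inf
        if l >= 0:
            d = pt - c_ps[l]
            if d <= caliper:
                # equal-ps controls form a contiguous sorted run ordered by
                # original index; the ascending-index tie-break wants the
                # leftmost alive member of the run
                while l > 0:
                    l2 = find_left(l) - 1
                    if l2 >= 0 and c_ps[l2] == c_ps[l]:
                        l = l2
                    else:
                        break
                best, best_d = l, d
        if r < m:
            d = c_ps[r] - pt
            if d <= caliper and (
                d < best_d or (d == best_d and c_order[r] < c_order[best])
            ):
                best, best_d = r, d
        if best >= 0:
            pairs.append((t, c_order[best]))
            kill(best)
        # unmatched treated units are dropped
    return (
        np.asarray(pairs, dtype=np.intp)
        if pairs
        else np.empty((0, 2), dtype=np.intp)
    )


def estimate_all_methods(
    cohort: Cohort,
    calipers: Sequence[float] = (0.001, 0.01, 0.1),
    methods: Optional[Sequence[str]] = None,
) -> tuple[list[FitResult], dict[str, AdjustmentArtifact]]:
    """Run the five strategies on one cohort (or the subset in ``methods``).

    Returns the three regression fits, the IPTW fit, and one PSM fit per
    caliper, plus the propensity-score artifacts.  Per-method failures
    are recorded as not-converged results; they never abort the others.
    """
    from .diagnostics import common_support

    wanted = set(METHODS if methods is None else methods)
    unknown = wanted - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    fits: list[FitResult] = []
    for method, covset in REGRESSION_COVARIATES.items():
        if method in wanted:
            fits.append(fit_logistic(cohort, covset, method=method))

    artifacts: dict[str, AdjustmentArtifact] = {}
    if not wanted & {"iptw", "psm"}:
        return fits, artifacts
    try:
        ps = fit_probit_propensity(cohort)
    except ValueError:
        if "iptw" in wanted:
            fits.append(_failed_fit("iptw", cohort.n))
        if "psm" in wanted:
            for cal in calipers:
                fits.append(_failed_fit("psm", 0, caliper=cal))
        return fits, artifacts

    support = common_support(ps, cohort.T)
    if "iptw" in wanted:
        w = compute_iptw_weights(ps, cohort.T)
        artifacts["iptw"] = AdjustmentArtifact(
            propensity_scores=ps, weights=w, common_support_prop=support
        )
        fits.append(fit_logistic(cohort, (), weights=w, method="iptw"))

    for cal in calipers if "psm" in wanted else ():
        pairs = greedy_match(ps, cohort.T, cal)
        art = AdjustmentArtifact(
            propensity_scores=ps,
            matched_pairs=pairs,
            caliper=cal,
            common_support_prop=support,
        )
        artifacts[f"psm_{cal:g}"] = art
        idx = art.matched_indices()
        if idx.size == 0:
            fits.append(_failed_fit("psm", 0, caliper=cal))
            continue
        fits.append(fit_logistic(cohort, (), subset=idx, method="psm", caliper=cal))
    return fits, artifacts
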