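"""Standardized risk ratios and E-values.

A logistic coefficient is a conditional log odds ratio; to report a
marginal risk ratio the fitted model is standardized (g-computation):
predict every analytic-sample patient's cure probability with treatment
forced on and forced off, average each (with the method's weights), and
take the ratio.

The E-value of VanderWeele and Ding is the minimum strength of
association, on the risk-ratio scale, that an unmeasured confounder
would need with both treatment and outcome to fully explain away the
observed association:

    E = RR* + sqrt(RR* * (RR* - 1)),   RR* = max(RR, 1/RR)

(Some write-ups misprint the radicand as RR*(1 - RR), which is negative
for RR > 1; the form above is the actual statistic.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .dgp import Cohort
from .estimators import FitResult

__all__ = ["EValueResult", "standardized_rr", "evalue"]


@dataclass(frozen=True)
class EValueResult:
    rr: float
    evalue: float
    rr_was_inverted: bool


def standardized_rr(
    fit: FitResult,
    cohort: Cohort,
    weights: Optional[np.ndarray] = None,
    pairs: Optional[np.ndarray] = None,
    at_covariate_means: bool = False,
) -> float:
    """Marginal risk ratio from a fitted logistic model by standardization.

    The analytic sample follows the fit's method: the full cohort for
    plain and weighted regressions (with IPTW weights applied to the
    averaging), the matched subset for matched fits.
    ``at_covariate_means`` instead evaluates both arms at the analytic
    sample's covariate means (a conditional, not marginal, contrast).
    """
    if not fit.converged:
        raise ValueError("cannot standardize a non-converged fit")
    idx = None
    if pairs is not None:
        idx = np.asarray(pairs, dtype=np.intp).ravel()

    def arm_mean(t_value: float) -> float:
        lp = np.full(cohort.n, fit.coef["const"] + fit.coef["T"] * t_value)
        for name in fit.covariate_set:
            lp += fit.coef[name] * cohort.column(name)
        w = None if weights is None else np.asarray(weights, dtype=float)
        if idx is not None:
            lp = lp[idx]
            w = None if w is None else w[idx]
        if at_covariate_means:
            return float(expit(np.average(lp, weights=w)))
        return float(np.average(expit(lp), weights=w))

    p1 = arm_mean(1.0)
    p0 = arm_mean(0.0)
    if p0 <= 0.0:
        raise ValueError("degenerate baseline risk; cannot form a risk ratio")
    return p1 / p0


def evalue(rr: float) -> EValueResult:
    """E-value for a point-estimate risk ratio; protective RRs are inverted first."""
    rr = float(rr)
    if rr <= 0.0 or not np.isfinite(rr):
        raise ValueError(f"risk ratio must be a positive finite number; got {rr}")
    inverted = rr < 1.0
    rr_star = 1.0 / rr if inverted else rr
    e = rr_star + np.sqrt(rr_star * (rr_star - 1.0))
    return EValueResult(rr=rr, evalue=float(e), rr_was_inverted=inverted)
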