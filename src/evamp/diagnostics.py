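"""Balance, common-support, and bias diagnostics.

The standardized mean difference (SMD) is the workhorse balance metric:
the absolute between-arm mean difference divided by the pooled standard
deviation sqrt((s_T^2 + s_C^2) / 2).  For weighted samples the means and
variances are frequency-weighted over the sample under analysis (the
post-adjustment convention); for matched samples the statistic is
computed on the matched subset only.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["smd", "common_support", "bias"]


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Frequency-weight mean and variance (matches expansion by integer weights)."""
    sw = w.sum()
    mean = float(np.dot(w, x) / sw)
    if sw <= 1:
        return mean, 0.0
    var = float(np.dot(w, (x - mean) ** 2) / (sw - 1.0))
    return mean, var


def smd(
    values: np.ndarray,
    T: np.ndarray,
    weights: Optional[np.ndarray] = None,
    pairs: Optional[np.ndarray] = None,
    signed: bool = False,
    pre_adjustment_sds: bool = False,
) -> float:
    """Standardized mean difference of ``values`` between treatment arms.

    ``weights`` restricts to a weighted sample (IPTW); ``pairs`` (an array
    of (treated, control) index pairs) restricts to the matched subset.
    By default the denominator pools the group SDs of the sample under
    analysis; ``pre_adjustment_sds`` standardizes by the unadjusted
    full-sample group SDs instead.  Zero pooled variance with equal means
    gives 0; with unequal means it is an error, since the difference is
    then unstandardizable.
    """
    x = np.asarray(values, dtype=float)
    T = np.asarray(T)
    pre_pooled = None
    if pre_adjustment_sds:
        v1 = np.var(x[T == 1], ddof=1) if (T == 1).sum() > 1 else 0.0
        v0 = np.var(x[T != 1], ddof=1) if (T != 1).sum() > 1 else 0.0
        pre_pooled = np.sqrt((v1 + v0) / 2.0)
    if pairs is not None:
        idx = np.asarray(pairs, dtype=np.intp).ravel()
        x, T = x[idx], T[idx]
        if weights is not None:
            weights = np.asarray(weights)[idx]
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    mask_t = T == 1
    if not mask_t.any() or mask_t.all():
        raise ValueError("both treatment arms must be nonempty for an SMD")
    m1, v1 = _weighted_mean_var(x[mask_t], w[mask_t])
    m0, v0 = _weighted_mean_var(x[~mask_t], w[~mask_t])
    pooled = np.sqrt((v1 + v0) / 2.0) if pre_pooled is None else pre_pooled
    diff = m1 - m0
    if pooled == 0.0:
        if diff == 0.0:
            return 0.0
        raise ValueError("zero pooled variance with unequal group means")
    out = diff / pooled
    return float(out if signed else abs(out))


def common_support(propensity_scores: np.ndarray, T: np.ndarray) -> float:
    """Fraction of all observations whose propensity score lies in the
    closed overlap region of the two arms' score ranges.

    The overlap region is [max of per-arm minima, min of per-arm maxima];
    endpoint ties count as inside.  An empty region gives 0.
    """
    ps = np.asarray(propensity_scores, dtype=float)
    T = np.asarray(T)
    ps_t, ps_c = ps[T == 1], ps[T != 1]
    if ps_t.size == 0 or ps_c.size == 0:
        raise ValueError("both treatment arms must be nonempty")
    lo = max(ps_t.min(), ps_c.min())
    hi = min(ps_t.max(), ps_c.max())
    if lo > hi:
        return 0.0
    return float(((ps >= lo) & (ps <= hi)).mean())


def bias(beta_T_true: float, beta_T_hat: float) -> float:
    """Estimation bias with the convention true minus estimate.

    An upwardly biased estimate therefore yields a *negative* bias; the
    convention is kept because the downstream bias-vs-E-value summaries
    use it, and only magnitudes and rankings matter there.
    """
    return float(beta_T_true) - float(beta_T_hat)
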