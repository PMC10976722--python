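"""Data-generating process for the confounded-treatment simulation.

The model describes a cohort of patients who self-select into a binary
treatment according to a latent net-utility rule and then experience a
binary "cure" outcome drawn from a logistic model.  One confounder
(``X_m``) is observed by the analyst; four more (``X_u1`` .. ``X_u4``)
are unobserved.  A single weight ``rho`` controls how strongly the
unobserved covariates are correlated with the observed one:

* ``X_m ~ U[0, 1]``
* ``X_ui = rho * X_m + (1 - rho) * mu_i`` for ``i in {1, 3, 4}``, with an
  independent fresh ``mu_i ~ U[0, 1]`` draw per covariate per patient
* ``X_u2 = 0.5 * X_u3 + 0.5 * mu_2`` with a further independent draw

Treatment utility:  ``Tx = V * beta_T - S + alpha * (X_m + X_u1 + X_u3 + X_u4)``
and ``T = 1`` iff ``Tx > 0`` (strict; ties go untreated).  The per-patient
treatment cost ``S`` is drawn from a configurable distribution (uniform
by default).

Cure probability: ``Pr(C) = expit(beta_T*T + beta_m*X_m + beta_u1*X_u1 + beta_u2*X_u2)``.

Note the asymmetry that drives the study: ``X_u3`` and ``X_u4`` affect
treatment only (near-instruments when correlated with ``X_m``), ``X_u2``
affects the outcome only but is correlated with ``X_u3``, and ``X_u1``
affects both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.special import expit

__all__ = [
    "SDist",
    "DGPParams",
    "Cohort",
    "DegenerateCohortWarning",
    "draw_covariates",
    "assign_treatment",
    "assign_outcome",
    "simulate_cohort",
]


class DegenerateCohortWarning(UserWarning):
    """Raised when a simulated cohort has an empty treatment or outcome class."""


@dataclass(frozen=True)
class SDist:
    """Distribution of the per-patient treatment cost ``S``.

    Only the families actually used by the study are supported; the point
    of the field is configurability of scale, not distributional zoo-keeping.
    """

    family: str = "uniform"
    low: float = 1.7
    high: float = 2.7

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.family == "constant":
            return np.full(n, self.low, dtype=float)
        raise ValueError(f"unknown S distribution family: {self.family!r}")


@dataclass(frozen=True)
class DGPParams:
    """Structural parameters of the data-generating process.

    ``beta_T`` plays a double role: it is the treatment effect on the
    cure log-odds and the weight on the value-of-cure ``V`` in the
    treatment utility.  ``alpha`` is the common weight of all four
    utility confounders.  The nuisance coefficients carry calibrated
    defaults (see docs/methods.md) chosen so that at ``rho = 0`` roughly
    half the cohort is treated and the marginal standardized risk ratio
    implied by ``beta_T = 0.2`` is about 1.07.
    """

    beta_T: float = 0.2
    alpha: float = 1.0
    beta_m: float = 0.4
    beta_u1: float = 0.4
    beta_u2: float = 0.4
    V: float = 1.0
    s_dist: SDist = field(default_factory=SDist)
    rho: float = 0.0
    intercept_C: float = 0.0
    n_obs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1); got {self.rho}")
        if self.n_obs < 1:
            raise ValueError(f"n_obs must be >= 1; got {self.n_obs}")

    def with_(self, **kwargs) -> "DGPParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


class CovariateBlock(NamedTuple):
    X_m: np.ndarray
    X_u1: np.ndarray
    X_u2: np.ndarray
    X_u3: np.ndarray
    X_u4: np.ndarray


COVARIATE_NAMES = ("X_m", "X_u1", "X_u2", "X_u3", "X_u4")
DEFAULT_OBSERVED = ("X_m", "T", "C")


@dataclass
class Cohort:
    """One simulated dataset: covariates, treatment and cure indicators.

    ``observed_columns`` records which columns the simulated analyst is
    allowed to use; estimation code that adjusts for observables only
    must restrict itself to this set.
    """

    X_m: np.ndarray
    X_u1: np.ndarray
    X_u2: np.ndarray
    X_u3: np.ndarray
    X_u4: np.ndarray
    T: np.ndarray
    C: np.ndarray
    params: DGPParams
    observed_columns: tuple = DEFAULT_OBSERVED
    degenerate: bool = False

    @property
    def n(self) -> int:
        return self.T.shape[0]

    def covariates(self) -> CovariateBlock:
        return CovariateBlock(self.X_m, self.X_u1, self.X_u2, self.X_u3, self.X_u4)

    def column(self, name: str) -> np.ndarray:
        if name in COVARIATE_NAMES or name in ("T", "C"):
            return getattr(self, name)
        raise KeyError(name)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {name: getattr(self, name) for name in (*COVARIATE_NAMES, "T", "C")}
        )

    def to_csv(self, path) -> None:
        """Flat CSV export (one row per patient) for debugging and cross-language checks."""
        self.to_frame().to_csv(path, index=False)


def draw_covariates(n: int, rho: float, rng: np.random.Generator) -> CovariateBlock:
    """Draw the observed confounder and the four correlated unobserved covariates.

    Each of ``X_u1``, ``X_u3``, ``X_u4`` mixes ``X_m`` with its own
    independent uniform draw; ``X_u2`` mixes ``X_u3`` with yet another
    independent draw.  All five covariates are convex combinations of
    U[0,1] variables and therefore bounded in [0, 1].
    """
    if n < 1:
        raise ValueError(f"n must be >= 1; got {n}")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must lie in [0, 1); got {rho}")
    X_m = rng.uniform(size=n)
    X_u1 = rho * X_m + (1.0 - rho) * rng.uniform(size=n)
    X_u3 = rho * X_m + (1.0 - rho) * rng.uniform(size=n)
    X_u4 = rho * X_m + (1.0 - rho) * rng.uniform(size=n)
    X_u2 = 0.5 * X_u3 + 0.5 * rng.uniform(size=n)
    return CovariateBlock(X_m, X_u1, X_u2, X_u3, X_u4)


def assign_treatment(
    cov: CovariateBlock, params: DGPParams, rng: np.random.Generator
) -> np.ndarray:
    """Latent-utility treatment rule: treat iff net utility is strictly positive."""
    S = params.s_dist.draw(cov.X_m.shape[0], rng)
    utility = (
        params.V * params.beta_T
        - S
        + params.alpha * (cov.X_m + cov.X_u1 + cov.X_u3 + cov.X_u4)
    )
    return (utility > 0).astype(np.int8)


def assign_outcome(
    cov: CovariateBlock, T: np.ndarray, params: DGPParams, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli cure outcome from the logistic model."""
    lp = (
        params.intercept_C
        + params.beta_T * T
        + params.beta_m * cov.X_m
        + params.beta_u1 * cov.X_u1
        + params.beta_u2 * cov.X_u2
    )
    return (rng.uniform(size=T.shape[0]) < expit(lp)).astype(np.int8)


def simulate_cohort(params: DGPParams, warn: bool = True) -> Cohort:
    """Generate one cohort from a single seeded RNG stream.

    Identical seed and parameters give a bit-identical cohort.  A cohort
    with an empty treatment arm or outcome class is flagged degenerate
    (and warned about) rather than silently passed downstream.
    """
    rng = np.random.default_rng(params.seed)
    cov = draw_covariates(params.n_obs, params.rho, rng)
    T = assign_treatment(cov, params, rng)
    C = assign_outcome(cov, T, params, rng)
    degenerate = bool(
        T.min() == T.max() or C.min() == C.max()
    )
    if degenerate and warn:
        warnings.warn(
            "degenerate cohort: a treatment arm or outcome class is empty",
            DegenerateCohortWarning,
            stacklevel=2,
        )
    return Cohort(*cov, T=T, C=C, params=params, degenerate=degenerate)
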