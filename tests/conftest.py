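import numpy as np
import pytest

from evamp.dgp import Cohort, DGPParams


def greedy_match_bruteforce(ps, T, caliper):
    """Direct enumeration of the greedy caliper matching procedure.

    Treated units in descending ps (ascending index on ties); for each,
    scan every unused control, keep the nearest within the caliper,
    breaking distance ties by the smaller control index.
    """
    ps = list(map(float, ps))
    n = len(ps)
    treated = sorted((i for i in range(n) if T[i] == 1), key=lambda i: (-ps[i], i))
    controls = [i for i in range(n) if T[i] != 1]
    used = set()
    pairs = []
    for t in treated:
        best, best_d = None, None
        for c in controls:
            if c in used:
                continue
            d = abs(ps[t] - ps[c])
            if d <= caliper and (best is None or d < best_d or (d == best_d and c < best)):
                best, best_d = c, d
        if best is not None:
            used.add(best)
            pairs.append((t, best))
    return pairs


def cohort_from_arrays(T, C, **covariates):
    """Assemble a Cohort from explicit vectors; missing covariates are zero."""
    T = np.asarray(T, dtype=np.int8)
    n = T.shape[0]
    cols = {
        name: np.asarray(covariates.get(name, np.zeros(n)), dtype=float)
        for name in ("X_m", "X_u1", "X_u2", "X_u3", "X_u4")
    }
    return Cohort(
        **cols,
        T=T,
        C=np.asarray(C, dtype=np.int8),
        params=DGPParams(n_obs=n),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort at rho=0.3, reused by read-only tests."""
    from evamp.dgp import simulate_cohort

    return simulate_cohort(DGPParams(rho=0.3, seed=42))
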