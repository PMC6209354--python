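import numpy as np
import pandas as pd
import pytest

from baytrips.config import BASE_TABLES, STUDY_CHOICE_COEFFICIENTS
from baytrips.varm import COEF_NAMES, VarmSpec, build_system


@pytest.fixture(scope="session")
def coefs():
    return STUDY_CHOICE_COEFFICIENTS

@pytest.fixture(scope="session")
def base_tables():
    return BASE_TABLES


#: sparse stable parameter set used across fitting/simulation tests
RECOVERY_PARAMS = {
    "b2_1": 0.4, "b2_2": 0.3,
    "w3_1": 0.6, "w3_2": 0.7, "w4_1": 0.3, "w4_2": 0.25,
    "v1": 0.5, "v2": 0.4,
}


@pytest.fixture(scope="session")
def recovery_params():
    return dict(RECOVERY_PARAMS)


def random_full_system(rng, n_bays=2):
    """Random stable full-parameter system on a small number of bays."""
    spec = VarmSpec(included=frozenset(COEF_NAMES), n_bays=n_bays)
    while True:
        params = {}
        for name in spec.names:
            if name.startswith("b"):
                params[name] = rng.uniform(-0.45, 0.45)
            elif name.startswith("w"):
                params[name] = rng.uniform(0.1, 0.8)
            else:
                params[name] = rng.uniform(0.3, 1.0)
        system = build_system(spec, params)
        M, _ = system.annual_map(0)
        if np.max(np.abs(np.linalg.eigvals(M))) < 0.95:
            return spec, params, system


def brute_force_loglik(system, y):
    """Joint-Gaussian log-density of a panel assembled directly from the
    state-space recursions — the independent oracle for the Kalman filter."""
    from scipy import stats

    T, n = y.shape
    dim = system.dim
    H = np.hstack([np.eye(n), np.zeros((n, n))])
    covz = np.zeros((T * dim, T * dim))
    covz[:dim, :dim] = system.stationary_cov(phase=0)
    for t in range(1, T):
        F = system.F[t % 2]
        for s in range(t):
            blk = F @ covz[(t - 1) * dim:t * dim, s * dim:(s + 1) * dim]
            covz[t * dim:(t + 1) * dim, s * dim:(s + 1) * dim] = blk
            covz[s * dim:(s + 1) * dim, t * dim:(t + 1) * dim] = blk.T
        covz[t * dim:(t + 1) * dim, t * dim:(t + 1) * dim] = (
            F @ covz[(t - 1) * dim:t * dim, (t - 1) * dim:t * dim] @ F.T
            + system.Q[t % 2]
        )
    Hbig = np.zeros((T * n, T * dim))
    R = np.zeros((T * n, T * n))
    for t in range(T):
        Hbig[t * n:(t + 1) * n, t * dim:(t + 1) * dim] = H
        R[t * n:(t + 1) * n, t * n:(t + 1) * n] = system.obs_cov(t % 2)
    covy = Hbig @ covz @ Hbig.T + R
    return stats.multivariate_normal(np.zeros(T * n), covy).logpdf(y.ravel())
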