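"""Periodic second-order vector-autoregressive state-space model of bay CPUE.

The latent abundance index x_{t,j} of a species in bay j evolves as

    x_{t,j} = b_{1,s} x_{t-0.5,j} + b_{2,s} x_{t-1,j}
              + w_{1,s} eps_{t,j-2} + w_{2,s} eps_{t,j-1} + w_{3,s} eps_{t,j}
              + w_{4,s} eps_{t,j+1} + w_{5,s} eps_{t,j+2}

with season s = 1 (spring) or 2 (fall) set by the target time t, unit-variance
independent process errors eps, and observations y_{t,j} = x_{t,j} + v_s e_{t,j}.
The five w's load shared shocks from the bay itself and its two neighbours on
either side in coastal order, producing spatially banded process-error
covariance; loadings that would refer to bays beyond the coastline are
structurally zero.

The full model has 16 coefficients.  The two observation scales (v1, v2) and
the two w4 loadings are always retained; nested candidates exclude at least
one of the remaining 12, giving 4095 specifications.  Each candidate is fitted
by maximizing the exact Gaussian likelihood with a Kalman filter over the
stacked state [x_t; x_{t-0.5}], from several randomized starts, and the best
model is chosen by BIC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .config import N_BAYS

__all__ = [
    "COEF_NAMES",
    "MANDATORY_COEFS",
    "OPTIONAL_COEFS",
    "VarmSpec",
    "StateSpaceSystem",
    "FittedModel",
    "enumerate_model_specs",
    "build_w_matrix",
    "build_system",
    "kalman_loglik",
    "fit_model",
    "select_best",
    "simulate_panel",
    "standard_errors",
]

#: All 16 coefficient names; index convention is name{k}_{season}.
COEF_NAMES: tuple[str, ...] = (
    "b1_1", "b1_2", "b2_1", "b2_2",
    "w1_1", "w2_1", "w3_1", "w4_1", "w5_1",
    "w1_2", "w2_2", "w3_2", "w4_2", "w5_2",
    "v1", "v2",
)

#: Coefficients present in every candidate model.
MANDATORY_COEFS: frozenset[str] = frozenset({"v1", "v2", "w4_1", "w4_2"})

OPTIONAL_COEFS: tuple[str, ...] = tuple(
    n for n in COEF_NAMES if n not in MANDATORY_COEFS
)

#: Parameter-vector sign constraints: process/observation scales are kept
#: non-negative (W enters only through W W', so signs are unidentified).
_NONNEG_PREFIXES = ("w", "v")


@dataclass(frozen=True)
class VarmSpec:
    """Inclusion mask over the 16 named coefficients."""

    included: frozenset[str]
    n_bays: int = N_BAYS

    def __post_init__(self) -> None:
        unknown = self.included - set(COEF_NAMES)
        if unknown:
            raise ValueError(f"unknown coefficient names: {sorted(unknown)}")
        missing = MANDATORY_COEFS - self.included
        if missing:
            raise ValueError(f"mandatory coefficients excluded: {sorted(missing)}")

    @property
    def names(self) -> tuple[str, ...]:
        """Included coefficients in canonical order."""
        return tuple(n for n in COEF_NAMES if n in self.included)

    @property
    def n_params(self) -> int:
        return len(self.included)

    def mask_tuple(self) -> tuple[int, ...]:
        return tuple(int(n in self.included) for n in COEF_NAMES)

    def coef(self, params: dict[str, float], name: str) -> float:
        return params.get(name, 0.0) if name in self.included else 0.0


FULL_SPEC = VarmSpec(included=frozenset(COEF_NAMES))


def enumerate_model_specs(n_optional: int = 12) -> list[VarmSpec]:
    """All nested candidates: mandatory coefficients plus a proper subset of
    the first ``n_optional`` optional ones (at least one excluded).

    Count is ``2**n_optional - 1``; the full model is not a candidate.
    """
    if not 1 <= n_optional <= len(OPTIONAL_COEFS):
        raise ValueError(f"n_optional must be in 1..{len(OPTIONAL_COEFS)}")
    opts = OPTIONAL_COEFS[:n_optional]
    specs = []
    for r in range(len(opts)):  # proper subsets only
        for subset in itertools.combinations(opts, r):
            specs.append(VarmSpec(included=frozenset(subset) | MANDATORY_COEFS))
    return specs


def build_w_matrix(w: np.ndarray, n_bays: int = N_BAYS) -> np.ndarray:
    """Banded process-noise loading matrix from (w1..w5).

    Row j loads w1 at column j-2, w2 at j-1, w3 at j, w4 at j+1, w5 at j+2;
    entries falling outside the coastline are structurally zero.
    """
    w = np.asarray(w, float)
    if w.shape != (5,):
        raise ValueError("w must have 5 entries (w1..w5)")
    W = np.zeros((n_bays, n_bays))
    for j in range(n_bays):
        for k, off in enumerate((-2, -1, 0, 1, 2)):
            col = j + off
            if 0 <= col < n_bays:
                W[j, col] = w[k]
    return W


@dataclass(frozen=True)
class StateSpaceSystem:
    """Per-season matrices of the stacked-state periodic linear system.

    The stacked state is z_t = [x_t; x_{t-0.5}] (dimension 2*n_bays); season
    index 0 is spring, 1 is fall, selected by the season of the *target* time.
    """

    F: tuple[np.ndarray, np.ndarray]  # transition per target season
    Q: tuple[np.ndarray, np.ndarray]  # process-noise covariance per season
    v: tuple[float, float]            # observation scale per season
    n_bays: int = N_BAYS

    @property
    def dim(self) -> int:
        return 2 * self.n_bays

    def obs_cov(self, season: int) -> np.ndarray:
        return self.v[season] ** 2 * np.eye(self.n_bays)

    def annual_map(self, phase: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Composite transition and accumulated noise over one year ending at
        ``phase`` (0 = spring, 1 = fall)."""
        other = 1 - phase
        M = self.F[phase] @ self.F[other]
        Q = self.Q[phase] + self.F[phase] @ self.Q[other] @ self.F[phase].T
        return M, Q

    def stationary_cov(self, phase: int = 0) -> np.ndarray:
        """Stationary stacked-state covariance at the given phase (discrete
        Lyapunov equation of the annual composite map)."""
        M, Q = self.annual_map(phase)
        rho = np.max(np.abs(np.linalg.eigvals(M)))
        if rho >= 1.0:
            raise ValueError(
                f"composite transition is non-stationary (spectral radius {rho:.3f}); "
                "use diffuse initialization"
            )
        return linalg.solve_discrete_lyapunov(M, Q)


def build_system(spec: VarmSpec, params: dict[str, float]) -> StateSpaceSystem:
    """Assemble the per-season system matrices from named coefficients.

    ``params`` must cover exactly the included coefficients; excluded ones
    contribute zero.
    """
    if set(params) != set(spec.included):
        extra = set(params) - spec.included
        missing = spec.included - set(params)
        raise ValueError(
            f"params/spec mismatch (extra: {sorted(extra)}, missing: {sorted(missing)})"
        )
    n = spec.n_bays
    I = np.eye(n)
    Fs, Qs, vs = [], [], []
    for s in (1, 2):
        b1 = spec.coef(params, f"b1_{s}")
        b2 = spec.coef(params, f"b2_{s}")
        w = np.array([spec.coef(params, f"w{k}_{s}") for k in range(1, 6)])
        W = build_w_matrix(w, n)
        F = np.block([[b1 * I, b2 * I], [I, np.zeros((n, n))]])
        Q = np.zeros((2 * n, 2 * n))
        Q[:n, :n] = W @ W.T
        v = spec.coef(params, f"v{s}")
        if v <= 0:
            raise ValueError(f"observation scale v{s} must be positive")
        Fs.append(F)
        Qs.append(Q)
        vs.append(v)
    return StateSpaceSystem(F=(Fs[0], Fs[1]), Q=(Qs[0], Qs[1]), v=(vs[0], vs[1]), n_bays=n)


def kalman_loglik(
    system: StateSpaceSystem,
    panel_values: np.ndarray,
    initialization: str = "stationary",
    diffuse_variance: float = 1e7,
    steady_tol: float = 1e-11,
) -> float:
    """Exact Gaussian log-likelihood of a season-alternating panel.

    ``panel_values`` has one row per half-year step starting with spring;
    NaN cells are treated as missing and skipped in the update.  The prior
    for the first (spring) state is the stationary distribution of the
    composite annual map, or a zero-mean diffuse prior on request.
    """
    y = np.asarray(panel_values, float)
    n_steps, n = y.shape
    if n != system.n_bays:
        raise ValueError("panel width does not match the system")
    dim = system.dim
    H = np.hstack([np.eye(n), np.zeros((n, n))])
    log2pi = np.log(2 * np.pi)

    if initialization == "stationary":
        P = system.stationary_cov(phase=0)
    elif initialization == "diffuse":
        P = diffuse_variance * np.eye(dim)
    else:
        raise ValueError("initialization must be 'stationary' or 'diffuse'")
    m = np.zeros(dim)

    # The periodic Riccati recursion converges geometrically; once the prior
    # covariance at a phase repeats (fully-observed rows only), the per-phase
    # gain and innovation covariance are frozen and each later step costs a
    # single matrix-vector product.
    cache: list[dict | None] = [None, None]
    steady = [False, False]

    ll = 0.0
    for t in range(n_steps):
        season = t % 2
        fully_observed = bool(np.all(np.isfinite(y[t])))
        if t > 0:
            F = system.F[season]
            m = F @ m
            if steady[season] and fully_observed:
                c = cache[season]
                innov = y[t] - m[:n]
                ll += -0.5 * (n * log2pi + c["logdet"] + innov @ c["Sinv"] @ innov)
                m = m + c["K"] @ innov
                P = c["P_post"]
                continue
            P = F @ P @ F.T + system.Q[season]
        obs = np.flatnonzero(np.isfinite(y[t]))
        if not obs.size:
            continue
        P_prior = P
        Ht = H[obs]
        innov = y[t, obs] - Ht @ m
        S = Ht @ P @ Ht.T + system.v[season] ** 2 * np.eye(obs.size)
        S = 0.5 * (S + S.T)
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        Sinv = np.linalg.inv(S)
        ll += -0.5 * (obs.size * log2pi + logdet + innov @ Sinv @ innov)
        K = P @ Ht.T @ Sinv
        m = m + K @ innov
        P = P - K @ Ht @ P
        P = 0.5 * (P + P.T)
        if fully_observed and t > 0:
            prev = cache[season]
            if prev is not None and np.max(np.abs(P_prior - prev["P_prior"])) < steady_tol:
                steady[season] = True
            cache[season] = {
                "P_prior": P_prior, "P_post": P, "Sinv": Sinv,
                "logdet": logdet, "K": K,
            }
    return float(ll)


@dataclass(frozen=True)
class FittedModel:
    """A fitted candidate with its likelihood and BIC."""

    spec: VarmSpec
    params: dict[str, float]
    loglik: float
    n_obs: int
    converged: bool
    start_index: int = -1

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)


def _unpack(spec: VarmSpec, x: np.ndarray) -> dict[str, float]:
    return dict(zip(spec.names, x))


def _neg_loglik(x: np.ndarray, spec: VarmSpec, y: np.ndarray, initialization: str) -> float:
    params = _unpack(spec, x)
    try:
        system = build_system(spec, params)
        ll = kalman_loglik(system, y, initialization=initialization)
    except (ValueError, linalg.LinAlgError):
        return 1e12
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _bounds(spec: VarmSpec) -> list[tuple[float | None, float | None]]:
    out = []
    for name in spec.names:
        if name.startswith("v"):
            out.append((1e-4, None))
        elif name.startswith("w"):
            out.append((0.0, None))
        else:
            out.append((None, None))
    return out


def fit_model(
    spec: VarmSpec,
    panel_values: np.ndarray,
    n_starts: int = 5,
    seed: int | np.random.Generator = 0,
    initialization: str = "stationary",
) -> FittedModel:
    """Maximum-likelihood fit from several randomized starts.

    Autoregressive coefficients start in U(-0.5, 0.5), scales in U(0.1, 1.0).
    Non-estimable models (no start converges) are returned with
    ``converged=False`` rather than raising.
    """
    y = np.asarray(panel_values, float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = spec.names
    bounds = _bounds(spec)
    best_x, best_ll, best_start = None, -np.inf, -1
    for i in range(n_starts):
        x0 = np.array([
            rng.uniform(0.1, 1.0) if n[0] in _NONNEG_PREFIXES else rng.uniform(-0.5, 0.5)
            for n in names
        ])
        res = optimize.minimize(
            _neg_loglik, x0, args=(spec, y, initialization),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500},
        )
        if res.success and -res.fun > best_ll and res.fun < 1e11:
            best_ll, best_x, best_start = -res.fun, res.x, i
    n_obs = int(np.isfinite(y).sum())
    if best_x is None:
        return FittedModel(
            spec=spec, params={}, loglik=-np.inf, n_obs=n_obs, converged=False
        )
    return FittedModel(
        spec=spec, params=_unpack(spec, best_x), loglik=best_ll,
        n_obs=n_obs, converged=True, start_index=best_start,
    )


def select_best(fits: list[FittedModel]) -> FittedModel:
    """Converged fit with minimal BIC; ties go to fewer parameters, then to
    the lexicographically smaller inclusion mask."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to select from")
    return min(converged, key=lambda f: (f.bic, f.n_params, f.spec.mask_tuple()))


def simulate_panel(
    fitted: FittedModel,
    n_steps: int = 70,
    burn_in: int = 20,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw an observation panel from a fitted model.

    The initial stacked state is drawn from the stationary distribution, a
    burn-in is iterated, then ``n_steps`` half-year rows (starting with
    spring) are emitted as y = x + v_s e.  Deterministic given the seed.
    """
    if not fitted.converged:
        raise ValueError("cannot simulate from a non-converged fit")
    system = build_system(fitted.spec, fitted.params)
    n = system.n_bays
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    P0 = system.stationary_cov(phase=0)  # raises on explosive dynamics
    L = np.linalg.cholesky(P0 + 1e-12 * np.eye(system.dim))
    z = L @ rng.standard_normal(system.dim)

    W = {
        s: build_w_matrix(
            [fitted.spec.coef(fitted.params, f"w{k}_{s + 1}") for k in range(1, 6)], n
        )
        for s in (0, 1)
    }
    b = {
        s: (
            fitted.spec.coef(fitted.params, f"b1_{s + 1}"),
            fitted.spec.coef(fitted.params, f"b2_{s + 1}"),
        )
        for s in (0, 1)
    }

    def step(z: np.ndarray, season: int) -> np.ndarray:
        b1, b2 = b[season]
        x_new = b1 * z[:n] + b2 * z[n:] + W[season] @ rng.standard_normal(n)
        return np.concatenate([x_new, z[:n]])

    # each burn-in year steps fall then spring, keeping z at the spring phase
    for _ in range(burn_in):
        z = step(z, 1)
        z = step(z, 0)

    y = np.empty((n_steps, n))
    for t in range(n_steps):
        if t > 0:
            z = step(z, t % 2)
        season = t % 2
        y[t] = z[:n] + system.v[season] * rng.standard_normal(n)
    return y


def standard_errors(fitted: FittedModel, panel_values: np.ndarray) -> dict[str, float]:
    """Asymptotic standard errors from the observed information matrix.

    The Hessian of the negative log-likelihood at the optimum is computed by
    central finite differences; a singular information matrix marks the model
    as not estimable.
    """
    from statsmodels.tools.numdiff import approx_hess

    y = np.asarray(panel_values, float)
    x = np.array([fitted.params[n] for n in fitted.spec.names])
    hess = approx_hess(x, _neg_loglik, args=(fitted.spec, y, "stationary"))
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise ValueError("observed information is singular; model not estimable") from exc
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise ValueError("observed information not positive definite at the optimum")
    return dict(zip(fitted.spec.names, np.sqrt(diag)))
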