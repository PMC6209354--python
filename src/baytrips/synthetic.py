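"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three model stages: trended CPUE panels
(log-scale polynomial trend per bay plus a stationary periodic-VAR
fluctuation, mimicking the observed monitoring series), standardized panels
drawn exactly from the state-space model (for estimator recovery tests), and
discrete site-choice records drawn from the conditional logit (for choice
estimation tests).  All generators are deterministic given a seed; each draws
from named substreams so adding one noise component does not shift the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BAYS, N_BAYS, SPECIES, ChoiceCoefficients
from .detrend import SeasonalCpuePanel
from .varm import MANDATORY_COEFS, FittedModel, VarmSpec, simulate_panel

__all__ = [
    "SyntheticConfig",
    "STUDY_LIKE_PARAMS",
    "params_to_model",
    "gen_varm_panel",
    "gen_trended_cpue",
    "gen_choice_dataset",
]

#: Sparse study-scale parameter values used as the default data-generating
#: process (autoregression on the one-year lag, banded process noise, sizable
#: observation error) — magnitudes typical of the fitted bay models.
STUDY_LIKE_PARAMS: dict[str, float] = {
    "b2_1": 0.33, "b2_2": 0.23,
    "w1_1": 0.27, "w3_1": 0.66, "w4_1": 0.42,
    "w1_2": 0.18, "w2_2": 0.28, "w3_2": 0.74, "w4_2": 0.30,
    "v1": 0.66, "v2": 0.34,
}

_SUBSTREAMS = {"varm": 1, "trend": 2, "choice": 3, "red_drum": 4, "spotted_seatrout": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SUBSTREAMS[stream]])


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and noise settings of the trended-CPUE generator.

    Trend coefficients are on the log-CPUE scale over the year index 1..n;
    ``fluctuation_scale`` multiplies the standardized stationary component
    before exponentiation and ``base_log_level`` sets the typical log CPUE.
    """

    n_years: int = 35
    n_bays: int = N_BAYS
    base_log_level: float = -1.5
    trend_slope_sd: float = 0.012
    trend_curvature_sd: float = 0.0006
    fluctuation_scale: float = 0.35
    varm_params: dict[str, float] = field(default_factory=lambda: dict(STUDY_LIKE_PARAMS))

    def __post_init__(self) -> None:
        if self.n_years < 4 or self.n_bays < 1:
            raise ValueError("panel shape must be positive and span several years")


def params_to_model(params: dict[str, float]) -> FittedModel:
    """Wrap explicit coefficient values as a (trivially converged) model."""
    included = frozenset(params) | MANDATORY_COEFS
    missing = MANDATORY_COEFS - set(params)
    if missing:
        raise ValueError(f"params must include the mandatory scales {sorted(missing)}")
    spec = VarmSpec(included=included)
    return FittedModel(spec=spec, params=dict(params), loglik=0.0, n_obs=1, converged=True)


def gen_varm_panel(
    params: dict[str, float], n_steps: int = 70, seed: int = 0, burn_in: int = 20
) -> np.ndarray:
    """Exact draw of an observation panel from the state-space model."""
    return simulate_panel(params_to_model(params), n_steps=n_steps, burn_in=burn_in, seed=seed)


def gen_trended_cpue(
    config: SyntheticConfig = SyntheticConfig(), seed: int = 0
) -> dict[str, SeasonalCpuePanel]:
    """Raw CPUE panel pair (one per species) with trends and stationary noise.

    Per species, a standardized stationary panel is drawn from the
    state-space model and each bay column is exponentiated around a
    bay-specific quadratic log-trend: strictly positive, trending, and
    stationary after de-trending.
    """
    panels = {}
    for sp in SPECIES:
        rng_t = _rng(seed, sp)
        z = gen_varm_panel(
            config.varm_params,
            n_steps=2 * config.n_years,
            seed=_rng(seed, "varm").integers(2**31 - 1) + _SUBSTREAMS[sp],
        )[:, : config.n_bays]
        t_year = np.repeat(1.0 + np.arange(config.n_years), 2)
        values = np.empty_like(z)
        for j in range(config.n_bays):
            slope = rng_t.normal(0.0, config.trend_slope_sd)
            curv = rng_t.normal(0.0, config.trend_curvature_sd)
            level = config.base_log_level + rng_t.normal(0.0, 0.3)
            trend = level + slope * t_year + curv * t_year**2
            values[:, j] = np.exp(trend + config.fluctuation_scale * z[:, j])
        panels[sp] = SeasonalCpuePanel(species=sp, values=values, stage="raw")
    return panels


def gen_choice_dataset(
    coefs: ChoiceCoefficients,
    sites: pd.DataFrame,
    n_records: int = 1000,
    seed: int = 0,
    distance_jitter: float = 0.3,
    catch_jitter: float = 0.3,
) -> pd.DataFrame:
    """Trip records drawn from the conditional-logit choice probabilities.

    ``sites`` has columns ``distance``, ``catch_red_drum``,
    ``catch_spotted_seatrout`` (one row per alternative).  Each record
    perturbs distances multiplicatively and catches log-normally (giving the
    across-trip covariate variation real intercept data have), computes the
    logit probabilities, and samples one chosen site.  Output is long-format
    with ``trip_id`` and a 0/1 ``chosen`` flag.
    """
    need = {"distance", "catch_red_drum", "catch_spotted_seatrout"}
    if not need <= set(sites.columns):
        raise ValueError(f"sites must have columns {sorted(need)}")
    n_sites = len(sites)
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    rng = _rng(seed, "choice")
    base_d = sites["distance"].to_numpy(float)
    base_c = {
        sp: sites[f"catch_{sp}"].to_numpy(float) for sp in SPECIES
    }
    rows = []
    for i in range(n_records):
        d = base_d * rng.uniform(1.0 - distance_jitter, 1.0 + distance_jitter, n_sites)
        c = {
            sp: base_c[sp] * rng.lognormal(0.0, catch_jitter, n_sites) for sp in SPECIES
        }
        u = coefs.beta_d * d + coefs.beta_cR * c["red_drum"] + coefs.beta_cS * c["spotted_seatrout"]
        p = np.exp(u - u.max())
        p /= p.sum()
        choice = rng.choice(n_sites, p=p)
        for j in range(n_sites):
            rows.append(
                {
                    "trip_id": i,
                    "site": j,
                    "chosen": int(j == choice),
                    "distance": d[j],
                    "catch_red_drum": c["red_drum"][j],
                    "catch_spotted_seatrout": c["spotted_seatrout"][j],
                }
            )
    return pd.DataFrame(rows)
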