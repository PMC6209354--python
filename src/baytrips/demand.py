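"""Random-utility site choice, participation, and catch elasticities.

An angler who takes a trip chooses among the seven bays with conditional-logit
probabilities driven by distance and the expected catch of the two species,

    P_j = exp(beta_d * d_j + beta_cR * c_jR + beta_cS * c_jS) / sum_k exp(...).

Because the choice coefficients come from anglers elsewhere in the Gulf, the
model is calibrated to Texas by solving for the distance vector a hypothetical
representative angler would have to face for the predicted shares to equal the
observed trip shares (anchored at 100 miles for Galveston).  Participation is
a logistic function of the inclusive value IV = ln sum_k exp(utility_k), with
dissimilarity coefficient lambda calibrated from willingness to pay, and the
elasticity of trips to bay j with respect to its catch splits into a
participation component and a site-choice component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax

from .config import (
    ANNUAL_FISHING_DAYS,
    BAYS,
    N_BAYS,
    SEASON_DAYS,
    SPECIES,
    WTP_PER_TRIP,
    BaseSeasonTable,
    CatchWeights,
    ChoiceCoefficients,
)

__all__ = [
    "DistanceVector",
    "DemandScenario",
    "base_catch_rates",
    "site_utilities",
    "site_choice_probs",
    "calibrate_distance_vector",
    "expected_catch",
    "inclusive_value",
    "lambda_from_wtp",
    "base_participation",
    "delta_trip_probability",
    "trip_elasticity",
    "elasticity_table",
    "estimate_choice_coefficients",
]


@dataclass(frozen=True)
class DistanceVector:
    """Calibrated representative-angler distances, miles, coastal bay order."""

    season: str
    miles: np.ndarray
    anchor: float = 100.0

    def __post_init__(self) -> None:
        miles = np.asarray(self.miles, float)
        object.__setattr__(self, "miles", miles)
        if miles.shape != (N_BAYS,):
            raise ValueError(f"distance vector must have {N_BAYS} entries")
        if np.any(miles <= 0):
            raise ValueError("distances must be positive")
        if abs(miles[0] - self.anchor) > 1e-9:
            raise ValueError("first entry must equal the anchor distance")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bay": list(BAYS), "miles": self.miles})


@dataclass(frozen=True)
class DemandScenario:
    """Constants of one participation scenario.

    lambda_ scales the participation response to inclusive value; it is tied
    to the travel-cost assumption via lambda = -(beta_d / cost_per_mile) * WTP.
    """

    cost_per_mile: float
    wtp: float
    lambda_: float
    pt_high: float
    pt_low: float
    annual_days: float = ANNUAL_FISHING_DAYS
    days_high: int = SEASON_DAYS["high"]
    days_low: int = SEASON_DAYS["low"]

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        for p in (self.pt_high, self.pt_low):
            if not 0 < p < 1:
                raise ValueError("base participation probabilities must be in (0,1)")

    def pt_base(self, season: str) -> float:
        return self.pt_high if season == "high" else self.pt_low


def base_catch_rates(base: BaseSeasonTable) -> dict[str, np.ndarray]:
    """Expected fish per trip by bay and species: harvest divided by trips."""
    return {sp: base.harvest(sp) / base.trips for sp in SPECIES}


def site_utilities(
    catch: dict[str, np.ndarray],
    distances: DistanceVector | np.ndarray,
    coefs: ChoiceCoefficients,
) -> np.ndarray:
    miles = distances.miles if isinstance(distances, DistanceVector) else np.asarray(distances, float)
    u = coefs.beta_d * miles
    for sp in SPECIES:
        if sp in catch:
            u = u + coefs.beta_c(sp) * np.asarray(catch[sp], float)
    return u


def site_choice_probs(
    catch: dict[str, np.ndarray],
    distances: DistanceVector | np.ndarray,
    coefs: ChoiceCoefficients,
) -> np.ndarray:
    """Conditional-logit bay-choice probabilities (overflow-safe)."""
    return softmax(site_utilities(catch, distances, coefs))


def inclusive_value(
    catch: dict[str, np.ndarray],
    distances: DistanceVector | np.ndarray,
    coefs: ChoiceCoefficients,
) -> float:
    """Log-sum of exponentiated site utilities — the expected utility of a trip."""
    return float(logsumexp(site_utilities(catch, distances, coefs)))


def calibrate_distance_vector(
    base: BaseSeasonTable,
    coefs: ChoiceCoefficients,
    d1: float = 100.0,
) -> DistanceVector:
    """Distances that make predicted shares equal observed trip shares.

    Writing D_j = exp(beta_d d_j) and C_j = exp(beta_cR c_jR + beta_cS c_jS),
    share matching gives D_j = (T_j/T_1)(C_1/C_j) D_1, hence

        d_j = d1 + [ln(T_j/T_1) + ln C_1 - ln C_j] / beta_d.

    The anchor d1 is arbitrary (shares are invariant to a common shift).
    """
    if coefs.beta_d == 0:
        raise ValueError("beta_d = 0: the share-matching system is unsolvable")
    rates = base_catch_rates(base)
    lnC = coefs.beta_cR * rates["red_drum"] + coefs.beta_cS * rates["spotted_seatrout"]
    T = base.trips
    miles = d1 + (np.log(T / T[0]) + lnC[0] - lnC) / coefs.beta_d
    return DistanceVector(season=base.season, miles=miles, anchor=d1)


def expected_catch(
    observed: np.ndarray,
    base_rates: np.ndarray,
    weights: CatchWeights,
    site_distances: np.ndarray | None = None,
    prev_wave: np.ndarray | None = None,
    prev_year: np.ndarray | None = None,
) -> np.ndarray:
    """Smoothed catch expectation: weighted average of catch anomalies.

    Each site's expectation is its long-run rate plus a weighted mean of
    observed anomalies (c_k - cbar_k): the current own-site observation has
    weight one; other sites are discounted geometrically with distance,
    observations from the previous wave by the wave weight, and those from
    the same wave one year earlier by the year weight.  With no distance
    matrix the smoother uses only each site's own history.
    """
    observed = np.asarray(observed, float)
    base_rates = np.asarray(base_rates, float)
    n = len(base_rates)
    if site_distances is None:
        site_distances = np.full((n, n), np.inf)
        np.fill_diagonal(site_distances, 0.0)
    dist_w = (1.0 - weights.distance_decay) ** np.asarray(site_distances, float)
    if weights.distance_decay == 0.0:
        dist_w = np.where(np.isinf(site_distances), 0.0, 1.0)
        np.fill_diagonal(dist_w, 1.0)

    layers = [(observed, 1.0)]
    if prev_wave is not None:
        layers.append((np.asarray(prev_wave, float), weights.wave_weight))
    if prev_year is not None:
        layers.append((np.asarray(prev_year, float), weights.year_weight))

    out = np.empty(n)
    for j in range(n):
        num = den = 0.0
        for values, time_w in layers:
            w = dist_w[j] * time_w
            num += float(np.sum(w * (values - base_rates)))
            den += float(np.sum(w))
        out[j] = base_rates[j] + (num / den if den > 0 else 0.0)
    return out


def lambda_from_wtp(
    beta_d: float, wtp: float = WTP_PER_TRIP, cost_per_mile: float = 1.0
) -> float:
    """Dissimilarity coefficient from willingness to pay.

    The distance coefficient is a travel-cost coefficient only at $1 per
    one-way mile; at other costs it is rescaled, so
    lambda = -(beta_d / cost_per_mile) * WTP.
    """
    if cost_per_mile <= 0:
        raise ValueError("cost_per_mile must be positive")
    if wtp < 0:
        raise ValueError("wtp must be non-negative")
    return -(beta_d / cost_per_mile) * wtp


def base_participation(
    trips_high: float,
    trips_low: float,
    annual_days: float = ANNUAL_FISHING_DAYS,
    days_high: int = SEASON_DAYS["high"],
    days_low: int = SEASON_DAYS["low"],
) -> tuple[float, float]:
    """Split the annual daily trip probability across the two seasons.

    The annual probability (annual_days / 365) is allocated proportionally to
    the seasonal trip totals; the day-weighted average of the two seasonal
    probabilities recovers the annual rate exactly.
    """
    if trips_high <= 0:
        raise ValueError("trips_high must be positive")
    if trips_low < 0 or annual_days <= 0 or days_high <= 0 or days_low <= 0:
        raise ValueError("trip totals and day counts must be positive")
    pt_high = (annual_days / 365.0) * (365.0 / days_high) * (
        trips_high / (trips_high + trips_low)
    )
    pt_low = (trips_low / trips_high) * pt_high * (days_high / days_low)
    return pt_high, pt_low


def delta_trip_probability(
    iv: float,
    iv_base: float,
    pt_base: float,
    lambda_: float,
    exact: bool = False,
) -> float:
    """Change in participation probability for a change in inclusive value.

    Default is the first-order approximation
    dP_T = lambda * (1 - P_T) * P_T * (IV - IV_base).  The exact mode
    recovers the logistic intercept alpha = logit(P_T) - lambda * IV_base and
    returns the exact difference of logistic probabilities.
    """
    if not 0 < pt_base < 1:
        raise ValueError("pt_base must be in (0, 1)")
    if not exact:
        return lambda_ * (1.0 - pt_base) * pt_base * (iv - iv_base)
    alpha = np.log(pt_base / (1.0 - pt_base)) - lambda_ * iv_base
    pt_new = 1.0 / (1.0 + np.exp(-(alpha + lambda_ * iv)))
    return float(pt_new - pt_base)


def trip_elasticity(
    coefs: ChoiceCoefficients,
    lambda_: float,
    pt: float,
    pj: float,
    cj: float,
    species: str,
) -> tuple[float, float, float]:
    """Elasticity of trips to bay j with respect to its catch of one species.

    Returns (total, participation component, site-choice component):

        eps_T   = lambda * (1 - P_T) * beta_c * P_j * c_j
        eps_jc  = beta_c * c_j * (1 - P_j)
    """
    if not 0 < pt < 1 or not 0 < pj < 1:
        raise ValueError("pt and pj must be in (0, 1)")
    if cj < 0:
        raise ValueError("cj must be non-negative")
    beta_c = coefs.beta_c(species)
    eps_part = lambda_ * (1.0 - pt) * beta_c * pj * cj
    eps_site = beta_c * cj * (1.0 - pj)
    return eps_part + eps_site, eps_part, eps_site


def elasticity_table(
    base_tables: dict[str, BaseSeasonTable],
    coefs: ChoiceCoefficients,
    cost_per_mile: float,
    wtp: float = WTP_PER_TRIP,
) -> pd.DataFrame:
    """Per-bay/season/species trip-catch elasticities at base levels.

    Catch rates are the base harvest-per-trip values, P_j the observed trip
    shares, and P_T the season's base participation probability.
    """
    lam = lambda_from_wtp(coefs.beta_d, wtp, cost_per_mile)
    pt_high, pt_low = base_participation(
        float(base_tables["high"].trips.sum()), float(base_tables["low"].trips.sum())
    )
    pt = {"high": pt_high, "low": pt_low}
    rows = []
    for season, base in base_tables.items():
        rates = base_catch_rates(base)
        shares = base.trips / base.trips.sum()
        for sp in SPECIES:
            for j, bay in enumerate(BAYS):
                total, part, site = trip_elasticity(
                    coefs, lam, pt[season], float(shares[j]), float(rates[sp][j]), sp
                )
                rows.append(
                    {
                        "cost_per_mile": cost_per_mile,
                        "lambda": lam,
                        "season": season,
                        "species": sp,
                        "bay": bay,
                        "elasticity": total,
                        "participation_component": part,
                        "site_choice_component": site,
                    }
                )
    return pd.DataFrame(rows)


def estimate_choice_coefficients(records: pd.DataFrame) -> ChoiceCoefficients:
    """Fit the conditional logit to trip records by maximum likelihood.

    ``records`` is long-format with columns ``trip_id``, ``chosen`` (0/1, one
    per trip), ``distance``, ``catch_red_drum``, ``catch_spotted_seatrout``.
    Standard errors come from the inverse observed information.  Raises if a
    covariate has no within-trip variation or the optimizer fails.
    """
    from statsmodels.discrete.conditional_models import ConditionalLogit

    required = {"trip_id", "chosen", "distance", "catch_red_drum", "catch_spotted_seatrout"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    n_trips = records["trip_id"].nunique()
    if n_trips < 50:
        raise ValueError("need at least 50 trip records")
    if (records.groupby("trip_id").size() < 2).any():
        raise ValueError("every trip needs at least 2 alternatives")

    exog_cols = ["distance", "catch_red_drum", "catch_spotted_seatrout"]
    demeaned = records.groupby("trip_id")[exog_cols].transform(lambda x: x - x.mean())
    degenerate = [c for c in exog_cols if np.allclose(demeaned[c], 0.0)]
    if degenerate:
        raise ValueError(f"no within-trip variation in {degenerate}; coefficients inestimable")

    model = ConditionalLogit(
        records["chosen"].to_numpy(),
        records[exog_cols].to_numpy(),
        groups=records["trip_id"].to_numpy(),
    )
    try:
        res = model.fit(disp=False)
    except Exception as exc:  # statsmodels raises various failure types
        raise ValueError(f"conditional-logit estimation failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise ValueError("estimation did not converge (non-finite standard errors)")
    beta = dict(zip(exog_cols, res.params))
    se = dict(zip(exog_cols, res.bse))
    return ChoiceCoefficients(
        beta_d=float(beta["distance"]),
        beta_cR=float(beta["catch_red_drum"]),
        beta_cS=float(beta["catch_spotted_seatrout"]),
        se_d=float(se["distance"]),
        se_cR=float(se["catch_red_drum"]),
        se_cS=float(se["catch_spotted_seatrout"]),
    )
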