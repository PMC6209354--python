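"""De-trending and standardization of the seasonal CPUE series.

Each of the 28 raw series (2 species x 7 bays x 2 seasons) is de-trended
separately: a polynomial in time of order up to three is selected by
leave-one-out cross-validation, and the residuals plus the series mean form
the de-trended series.  De-trended series are screened for stationarity with
the augmented Dickey-Fuller test (lag 0..3 by AIC).  The spring and fall
series of each bay are then interleaved into a 70 x 7 panel, logged, and
z-scored per bay column; the transform is recorded so simulated output can be
mapped back to the CPUE scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

from .config import BAYS, N_BAYS, SEASONS, SPECIES

__all__ = [
    "SeasonalSeries",
    "TrendFit",
    "StandardizeTransform",
    "SeasonalCpuePanel",
    "select_poly_order",
    "detrend_series",
    "adf_stationary",
    "adf_screening",
    "build_panel",
    "standardize_panel",
    "unstandardize_panel",
    "detrend_all",
]

#: Candidate polynomial orders for the trend fit; order 0 covers untrended series.
DEFAULT_CANDIDATE_ORDERS = (0, 1, 2, 3)

#: Relative floor applied before logging (fraction of the column mean).
LOG_FLOOR_FRACTION = 1e-3


@dataclass(frozen=True)
class SeasonalSeries:
    """One species/bay/season CPUE series on consecutive years."""

    species: str
    bay: str
    season: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.bay not in BAYS:
            raise ValueError(f"unknown bay {self.bay!r}")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if years.shape != values.shape or years.ndim != 1:
            raise ValueError("years and values must be matching 1-d arrays")
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("years must be consecutive with no gaps")
        # raw CPUE is non-negative (enforced at ingest); de-trended values
        # may dip below zero, so the container only requires finiteness
        if not np.all(np.isfinite(values)):
            raise ValueError("CPUE values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TrendFit:
    """Selected polynomial trend with per-order LOOCV scores."""

    order: int
    coefficients: np.ndarray  # ascending powers of the year index 1..n
    loocv_mse: dict[int, float]

    def predict(self, t: np.ndarray) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(t, float), self.coefficients)


@dataclass(frozen=True)
class StandardizeTransform:
    """Per-column log mean/sd and the pre-log floor, for inverting z-scores."""

    log_means: np.ndarray
    log_sds: np.ndarray
    floors: np.ndarray

    def __post_init__(self) -> None:
        for name in ("log_means", "log_sds", "floors"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not np.all(self.log_sds > 0):
            raise ValueError("log-scale standard deviations must be positive")
        if not np.all(self.floors > 0):
            raise ValueError("floors must be positive")


@dataclass(frozen=True)
class SeasonalCpuePanel:
    """70 x 7 seasonal panel for one species.

    Rows alternate spring/fall starting with spring (time index 1, 1.5, ...,
    35.5); columns are the bays in coastal order.  ``stage`` records whether
    values are raw CPUE, de-trended CPUE, or log/z-scored.
    """

    species: str
    values: np.ndarray
    stage: str
    start_year: int = 1982

    STAGES = ("raw", "detrended", "standardized")

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != N_BAYS:
            raise ValueError(f"panel must have {N_BAYS} bay columns")
        if values.shape[0] % 2 != 0:
            raise ValueError("panel must contain whole years (even row count)")
        if self.stage not in self.STAGES:
            raise ValueError(f"stage must be one of {self.STAGES}")

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def time_index(self) -> np.ndarray:
        return 1.0 + 0.5 * np.arange(self.n_steps)

    def season_of_row(self, i: int) -> str:
        return "spring" if i % 2 == 0 else "fall"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(BAYS))
        df.insert(0, "t", self.time_index)
        return df


def _poly_design(t: np.ndarray, order: int) -> np.ndarray:
    return np.vander(t, order + 1, increasing=True)


def _fit_poly(t: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    X = _poly_design(t, order)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def _loocv_mse(t: np.ndarray, y: np.ndarray, order: int) -> float:
    # hat-matrix shortcut: e_loo = e / (1 - h_ii) for OLS
    X = _poly_design(t, order)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    h = np.einsum("ij,ij->i", X @ np.linalg.pinv(X.T @ X), X)
    h = np.clip(h, None, 1 - 1e-12)
    return float(np.mean((resid / (1.0 - h)) ** 2))


def select_poly_order(
    series: SeasonalSeries,
    candidate_orders: Iterable[int] = DEFAULT_CANDIDATE_ORDERS,
) -> TrendFit:
    """Choose the trend order minimizing leave-one-out squared prediction error.

    Ties are broken toward the smaller order; the returned coefficients are
    the full-series OLS fit at the selected order, over the year index
    ``1..n``.
    """
    orders = sorted(set(int(k) for k in candidate_orders))
    if not orders:
        raise ValueError("candidate_orders must be non-empty")
    n = len(series)
    needed = max(orders) + 2
    if n < needed:
        raise ValueError(
            f"series of length {n} too short; need at least {needed} points "
            f"for order {max(orders)}"
        )
    t = 1.0 + np.arange(n)
    scores = {k: _loocv_mse(t, series.values, k) for k in orders}
    best = min(orders, key=lambda k: (scores[k], k))
    coef = _fit_poly(t, series.values, best)
    return TrendFit(order=best, coefficients=coef, loocv_mse=scores)


def detrend_series(series: SeasonalSeries, trend: TrendFit) -> SeasonalSeries:
    """Residuals from the fitted trend plus the series mean.

    Mean-preserving: the de-trended series has the same mean as the input
    (the OLS residuals sum to zero whenever the design includes a constant).
    """
    t = 1.0 + np.arange(len(series))
    resid = series.values - trend.predict(t)
    out = resid + series.values.mean()
    return replace(series, values=out)


def adf_stationary(
    series: SeasonalSeries | np.ndarray,
    max_lag: int = 3,
    alpha: float = 0.1,
) -> dict:
    """Augmented Dickey-Fuller screen with AIC lag selection.

    Regression includes a constant but no deterministic trend (series are
    already de-trended).  Returns ``{"stationary", "statistic", "pvalue",
    "chosen_lag"}``; ``stationary`` is True iff the unit-root null is
    rejected at level ``alpha``.
    """
    values = series.values if isinstance(series, SeasonalSeries) else np.asarray(series, float)
    if len(values) <= max_lag + 3:
        raise ValueError(f"series too short for ADF with max_lag={max_lag}")
    if np.ptp(values) == 0:
        raise ValueError("ADF test undefined for a constant series")
    stat, pvalue, usedlag, *_ = adfuller(
        values, maxlag=max_lag, regression="c", autolag="AIC"
    )
    return {
        "stationary": bool(pvalue < alpha),
        "statistic": float(stat),
        "pvalue": float(pvalue),
        "chosen_lag": int(usedlag),
    }


def adf_screening(
    series_list: Iterable[SeasonalSeries],
    max_lag: int = 3,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """ADF verdicts for a collection of series, one row per series."""
    rows = []
    for s in series_list:
        v = adf_stationary(s, max_lag=max_lag, alpha=alpha)
        rows.append(
            {"species": s.species, "bay": s.bay, "season": s.season, **v}
        )
    return pd.DataFrame(rows)


def build_panel(
    series_map: Mapping[tuple[str, str], SeasonalSeries],
    species: str,
    stage: str = "detrended",
) -> SeasonalCpuePanel:
    """Interleave spring/fall series per bay into the seasonal panel.

    ``series_map`` maps (bay, season) to a series; all series must share the
    same year span.  Row order is spring year 1, fall year 1, spring year 2, ...
    """
    lengths = {len(s) for s in series_map.values()}
    if len(lengths) != 1:
        raise ValueError("all series must cover the same years")
    n_years = lengths.pop()
    values = np.empty((2 * n_years, N_BAYS))
    start_years = set()
    for j, bay in enumerate(BAYS):
        for si, season in enumerate(SEASONS):
            s = series_map[(bay, season)]
            if s.species != species:
                raise ValueError(f"series for {bay}/{season} is not {species}")
            values[si::2, j] = s.values
            start_years.add(int(s.years[0]))
    if len(start_years) != 1:
        raise ValueError("all series must start in the same year")
    return SeasonalCpuePanel(
        species=species, values=values, stage=stage, start_year=start_years.pop()
    )


def standardize_panel(
    panel: SeasonalCpuePanel,
    floor_fraction: float = LOG_FLOOR_FRACTION,
) -> tuple[SeasonalCpuePanel, StandardizeTransform]:
    """Log and z-score each bay column of a de-trended panel.

    Values are floored at ``floor_fraction`` times the column mean before
    logging (the residual+mean construction can produce non-positive cells);
    the floor, log means and log sds are recorded for inversion.
    """
    if panel.stage != "detrended":
        raise ValueError("standardize_panel expects a de-trended panel")
    col_means = panel.values.mean(axis=0)
    if np.any(col_means <= 0):
        raise ValueError("column means must be positive to set the log floor")
    floors = floor_fraction * col_means
    floored = np.maximum(panel.values, floors[None, :])
    logs = np.log(floored)
    log_means = logs.mean(axis=0)
    log_sds = logs.std(axis=0, ddof=0)
    if np.any(log_sds <= 0):
        bad = [BAYS[j] for j in np.flatnonzero(log_sds <= 0)]
        raise ValueError(f"zero variance after logging in column(s) {bad}")
    z = (logs - log_means[None, :]) / log_sds[None, :]
    transform = StandardizeTransform(log_means=log_means, log_sds=log_sds, floors=floors)
    out = replace(panel, values=z, stage="standardized")
    return out, transform


def unstandardize_panel(
    panel: SeasonalCpuePanel, transform: StandardizeTransform
) -> SeasonalCpuePanel:
    """Invert the log/z-score transform: cell -> exp(z * sd + mean)."""
    if panel.stage != "standardized":
        raise ValueError("unstandardize_panel expects a standardized panel")
    if transform.log_means.shape != (panel.values.shape[1],):
        raise ValueError("transform dimensions do not match the panel")
    values = np.exp(panel.values * transform.log_sds[None, :] + transform.log_means[None, :])
    return replace(panel, values=values, stage="detrended")


def detrend_all(
    series_list: Iterable[SeasonalSeries],
    candidate_orders: Iterable[int] = DEFAULT_CANDIDATE_ORDERS,
) -> tuple[dict[tuple[str, str, str], SeasonalSeries], pd.DataFrame]:
    """De-trend every series; returns the de-trended map and a fit report.

    The report has one row per series with the selected order and its LOOCV
    mean squared error.
    """
    detrended: dict[tuple[str, str, str], SeasonalSeries] = {}
    rows = []
    for s in series_list:
        fit = select_poly_order(s, candidate_orders)
        d = detrend_series(s, fit)
        detrended[(s.species, s.bay, s.season)] = d
        rows.append(
            {
                "species": s.species,
                "bay": s.bay,
                "season": s.season,
                "order": fit.order,
                "loocv_mse": fit.loocv_mse[fit.order],
            }
        )
    return detrended, pd.DataFrame(rows)
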