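"""Readers and writers for the pipeline's text artifacts.

Long-format CPUE tables (year, season, bay, species, cpue) are validated and
split into per-series objects; seasonal panels travel as CSV with a leading
half-year time column and one column per bay; model specifications and fitted
parameters are serialized as JSON.  The supplementary spreadsheet layout of
the monitoring data (one column per bay/season block) can be ingested through
the same long-format path after a documented column mapping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BAYS, SEASONS, SPECIES, BaseSeasonTable
from .detrend import SeasonalCpuePanel, SeasonalSeries
from .varm import COEF_NAMES, FittedModel, VarmSpec

__all__ = [
    "load_config",
    "read_cpue_csv",
    "series_map_for_species",
    "write_panel_csv",
    "read_panel_csv",
    "read_base_table_csv",
    "write_model_json",
    "read_model_json",
]

_CPUE_COLUMNS = ("year", "season", "bay", "species", "cpue")

#: Allowed keys of the YAML run configuration, with defaults drawn from the
#: packaged study constants.  Unknown keys are rejected to prevent silent
#: constant drift (a typo must fail loudly, not fall back to a default).
_CONFIG_KEYS = {
    "beta_d", "beta_cR", "beta_cS",
    "wtp", "cost_per_mile_list", "annual_days", "days_high", "days_low",
}


def load_config(path: str | Path) -> dict:
    """Strict YAML config: choice coefficients and scenario constants.

    Returns a dict with a ``coefs`` entry (ChoiceCoefficients) plus the
    scenario constants, filling omitted keys from the packaged study values.
    """
    import yaml

    from .config import (
        ANNUAL_FISHING_DAYS,
        SEASON_DAYS,
        STUDY_CHOICE_COEFFICIENTS,
        WTP_PER_TRIP,
        ChoiceCoefficients,
    )

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    base = STUDY_CHOICE_COEFFICIENTS
    coefs = ChoiceCoefficients(
        beta_d=float(raw.get("beta_d", base.beta_d)),
        beta_cR=float(raw.get("beta_cR", base.beta_cR)),
        beta_cS=float(raw.get("beta_cS", base.beta_cS)),
    )
    out = {
        "coefs": coefs,
        "wtp": float(raw.get("wtp", WTP_PER_TRIP)),
        "cost_per_mile_list": tuple(
            float(c) for c in raw.get("cost_per_mile_list", (0.5, 1.0, 2.0))
        ),
        "annual_days": float(raw.get("annual_days", ANNUAL_FISHING_DAYS)),
        "days_high": int(raw.get("days_high", SEASON_DAYS["high"])),
        "days_low": int(raw.get("days_low", SEASON_DAYS["low"])),
    }
    for key in ("wtp", "annual_days", "days_high", "days_low"):
        if out[key] <= 0:
            raise ValueError(f"{path}: {key} must be positive")
    return out


def read_cpue_csv(path: str | Path) -> dict[tuple[str, str, str], SeasonalSeries]:
    """Load a long-format CPUE table into per-(species, bay, season) series.

    Validates the header, numeric CPUE, duplicate keys and year gaps; errors
    name the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    missing = set(_CPUE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    cpue = pd.to_numeric(df["cpue"], errors="coerce")
    bad = np.flatnonzero(cpue.isna() & df["cpue"].notna())
    if bad.size:
        raise ValueError(f"{path}: non-numeric cpue at row {bad[0] + 1}")
    neg = np.flatnonzero(cpue < 0)
    if neg.size:
        raise ValueError(f"{path}: negative cpue at row {neg[0] + 1}")
    df = df.assign(cpue=cpue)
    dup = df.duplicated(subset=["year", "season", "bay", "species"])
    if dup.any():
        raise ValueError(f"{path}: duplicate key at row {int(np.flatnonzero(dup)[0]) + 1}")
    out: dict[tuple[str, str, str], SeasonalSeries] = {}
    for (sp, bay, season), grp in df.groupby(["species", "bay", "season"], sort=False):
        grp = grp.sort_values("year")
        out[(sp, bay, season)] = SeasonalSeries(
            species=sp,
            bay=bay,
            season=season,
            years=grp["year"].to_numpy(int),
            values=grp["cpue"].to_numpy(float),
        )
    return out


def series_map_for_species(
    series: dict[tuple[str, str, str], SeasonalSeries], species: str
) -> dict[tuple[str, str], SeasonalSeries]:
    """Restrict a series collection to one species, keyed by (bay, season)."""
    out = {(b, s): v for (sp, b, s), v in series.items() if sp == species}
    expected = {(b, s) for b in BAYS for s in SEASONS}
    missing = expected - set(out)
    if missing:
        raise ValueError(f"species {species!r} missing series for {sorted(missing)}")
    return out


def write_panel_csv(panel: SeasonalCpuePanel, path: str | Path) -> None:
    df = panel.to_frame()
    df.insert(0, "stage", panel.stage)
    df.insert(0, "species", panel.species)
    df.to_csv(path, index=False)


def read_panel_csv(path: str | Path) -> SeasonalCpuePanel:
    df = pd.read_csv(path)
    need = {"species", "stage", "t", *BAYS}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    species = df["species"].iloc[0]
    stage = df["stage"].iloc[0]
    return SeasonalCpuePanel(
        species=species, values=df[list(BAYS)].to_numpy(float), stage=stage
    )


def read_base_table_csv(path: str | Path) -> dict[str, BaseSeasonTable]:
    """Base effort/landings CSV with columns season, bay, trips,
    harvest_red_drum, harvest_spotted_seatrout (bays in any order)."""
    df = pd.read_csv(path)
    need = {"season", "bay", "trips", "harvest_red_drum", "harvest_spotted_seatrout"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for season, grp in df.groupby("season"):
        grp = grp.set_index("bay").reindex(list(BAYS))
        if grp["trips"].isna().any():
            raise ValueError(f"{path}: season {season} does not cover all bays")
        out[season] = BaseSeasonTable(
            season=season,
            trips=grp["trips"].to_numpy(float),
            harvest_red_drum=grp["harvest_red_drum"].to_numpy(float),
            harvest_spotted_seatrout=grp["harvest_spotted_seatrout"].to_numpy(float),
        )
    return out


def write_model_json(fitted: FittedModel, path: str | Path) -> None:
    payload = {
        "included": sorted(fitted.spec.included),
        "params": fitted.params,
        "loglik": fitted.loglik,
        "n_obs": fitted.n_obs,
        "bic": fitted.bic if fitted.converged else None,
        "converged": fitted.converged,
        "start_index": fitted.start_index,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model_json(path: str | Path) -> FittedModel:
    payload = json.loads(Path(path).read_text())
    unknown = set(payload["included"]) - set(COEF_NAMES)
    if unknown:
        raise ValueError(f"{path}: unknown coefficients {sorted(unknown)}")
    return FittedModel(
        spec=VarmSpec(included=frozenset(payload["included"])),
        params={k: float(v) for k, v in payload["params"].items()},
        loglik=float(payload["loglik"]),
        n_obs=int(payload["n_obs"]),
        converged=bool(payload["converged"]),
        start_index=int(payload.get("start_index", -1)),
    )
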