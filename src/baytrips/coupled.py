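"""Coupling simulated CPUE to angler demand: seasonal trip trajectories.

Spring monitoring CPUE informs anglers in the following summer (high season)
and fall CPUE in the following winter (low season).  Simulated gillnet CPUE
is anchored to recreational harvest-per-trip by proportional scaling, fed
through the site-choice model to reallocate trips across bays, and through
the inclusive value to move participation; the number of trip occasions per
season is backed out from the base tables so that holding catch at its
long-run mean reproduces the base trip counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    BAYS,
    N_BAYS,
    SPECIES,
    WTP_PER_TRIP,
    BaseSeasonTable,
    ChoiceCoefficients,
)
from .demand import (
    DemandScenario,
    DistanceVector,
    base_catch_rates,
    base_participation,
    calibrate_distance_vector,
    delta_trip_probability,
    inclusive_value,
    lambda_from_wtp,
    site_choice_probs,
)
from .detrend import SeasonalCpuePanel

__all__ = [
    "TripTrajectory",
    "map_seasons",
    "scale_to_recreational",
    "make_scenario",
    "simulate_trips",
    "run_scenarios",
    "plot_trajectories",
]

_SEASON_OF_ROW = {"spring": "high", "fall": "low"}


@dataclass(frozen=True)
class TripTrajectory:
    """Per-season trips by bay under one travel-cost scenario.

    ``frame`` is tidy with columns scenario, year, season, bay, trips, PT, Pj;
    ``n_occasions`` holds the fixed per-season trip-occasion totals and
    ``clamp_events`` counts season-steps where the linearized participation
    update left [0, 1] and was clamped.
    """

    scenario: DemandScenario
    frame: pd.DataFrame
    n_occasions: dict[str, float]
    clamp_events: int = 0

    def trips_matrix(self, season: str) -> np.ndarray:
        sub = self.frame[self.frame["season"] == season]
        return (
            sub.pivot(index="year", columns="bay", values="trips")
            .reindex(columns=list(BAYS))
            .to_numpy()
        )


def map_seasons(panel: SeasonalCpuePanel) -> dict[str, np.ndarray]:
    """Split a seasonal panel into high/low fishing-season catch matrices.

    Spring rows (even index) feed the high season of the same year; fall rows
    feed the low season.
    """
    return {
        "high": panel.values[0::2, :].copy(),
        "low": panel.values[1::2, :].copy(),
    }


def scale_to_recreational(
    sim_cpue: np.ndarray, base_rates: np.ndarray
) -> np.ndarray:
    """Anchor simulated gillnet CPUE to recreational catch per trip.

    Recreational catch is assumed proportional to monitoring CPUE, so each
    bay's series is rescaled to have long-run mean equal to the base
    harvest-per-trip rate: c_rec = cbar * sim / mean_t(sim).
    """
    sim = np.asarray(sim_cpue, float)
    base = np.asarray(base_rates, float)
    means = sim.mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("simulated CPUE must have positive per-bay means")
    return base[None, :] * sim / means[None, :]


def make_scenario(
    base_tables: dict[str, BaseSeasonTable],
    coefs: ChoiceCoefficients,
    cost_per_mile: float,
    wtp: float = WTP_PER_TRIP,
) -> DemandScenario:
    """Scenario constants for one travel-cost assumption."""
    pt_high, pt_low = base_participation(
        float(base_tables["high"].trips.sum()), float(base_tables["low"].trips.sum())
    )
    return DemandScenario(
        cost_per_mile=cost_per_mile,
        wtp=wtp,
        lambda_=lambda_from_wtp(coefs.beta_d, wtp, cost_per_mile),
        pt_high=pt_high,
        pt_low=pt_low,
    )


def simulate_trips(
    sim_red: SeasonalCpuePanel,
    sim_trout: SeasonalCpuePanel,
    base_tables: dict[str, BaseSeasonTable],
    coefs: ChoiceCoefficients,
    scenario: DemandScenario,
    distances: dict[str, DistanceVector] | None = None,
    exact_participation: bool = False,
) -> TripTrajectory:
    """Trip trajectory from a pair of simulated CPUE panels.

    Per season-step: simulated CPUE is anchored to base catch rates, bay
    probabilities come from the site-choice logit, participation moves with
    the inclusive value (linearized by default, clamped to [0, 1]), and
    trips_j = N_season * P_T * P_j with N_season backed out from the base
    tables.  At base catch rates the trajectory reproduces the base trips.
    """
    if sim_red.n_steps != sim_trout.n_steps:
        raise ValueError("species panels must be aligned")
    if distances is None:
        distances = {
            s: calibrate_distance_vector(base_tables[s], coefs) for s in ("high", "low")
        }
    catches = {"red_drum": map_seasons(sim_red), "spotted_seatrout": map_seasons(sim_trout)}

    rows = []
    n_occasions = {}
    clamps = 0
    for season in ("high", "low"):
        base = base_tables[season]
        rates = base_catch_rates(base)
        dist = distances[season]
        pt_base = scenario.pt_base(season)
        n_occasions[season] = float(base.trips.sum()) / pt_base
        iv_base = inclusive_value(rates, dist, coefs)

        rec = {
            sp: scale_to_recreational(catches[sp][season], rates[sp]) for sp in SPECIES
        }
        n_years = rec["red_drum"].shape[0]
        for t in range(n_years):
            step_catch = {sp: rec[sp][t] for sp in SPECIES}
            pj = site_choice_probs(step_catch, dist, coefs)
            iv = inclusive_value(step_catch, dist, coefs)
            pt = pt_base + delta_trip_probability(
                iv, iv_base, pt_base, scenario.lambda_, exact=exact_participation
            )
            if not 0.0 <= pt <= 1.0:
                clamps += 1
                pt = float(np.clip(pt, 0.0, 1.0))
            trips = n_occasions[season] * pt * pj
            for j, bay in enumerate(BAYS):
                rows.append(
                    {
                        "scenario": scenario.cost_per_mile,
                        "year": t + 1,
                        "season": season,
                        "bay": bay,
                        "trips": trips[j],
                        "PT": pt,
                        "Pj": pj[j],
                    }
                )
    return TripTrajectory(
        scenario=scenario,
        frame=pd.DataFrame(rows),
        n_occasions=n_occasions,
        clamp_events=clamps,
    )


def run_scenarios(
    sim_red: SeasonalCpuePanel,
    sim_trout: SeasonalCpuePanel,
    base_tables: dict[str, BaseSeasonTable],
    coefs: ChoiceCoefficients,
    cost_per_mile_list: tuple[float, ...] = (0.5, 1.0, 2.0),
    wtp: float = WTP_PER_TRIP,
) -> list[TripTrajectory]:
    """One trajectory per travel-cost value, sharing the same CPUE panels."""
    out = []
    for cpm in cost_per_mile_list:
        scenario = make_scenario(base_tables, coefs, cpm, wtp)
        out.append(simulate_trips(sim_red, sim_trout, base_tables, coefs, scenario))
    return out


def summarize_trajectory(traj: TripTrajectory) -> pd.DataFrame:
    """Per-bay/season mean, sd and CV of trips for one scenario."""
    g = traj.frame.groupby(["season", "bay"], sort=False)["trips"]
    out = g.agg(["mean", "std"]).reset_index()
    out.insert(0, "cost_per_mile", traj.scenario.cost_per_mile)
    out["cv"] = out["std"] / out["mean"]
    return out


def plot_trajectories(trajectories: list[TripTrajectory], path=None):
    """Trip trajectories per bay, one panel per (season, scenario)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(trajectories)
    fig, axes = plt.subplots(2, n, figsize=(4 * n, 6), squeeze=False, sharey="row")
    for col, traj in enumerate(trajectories):
        for row, season in enumerate(("high", "low")):
            ax = axes[row][col]
            sub = traj.frame[traj.frame["season"] == season]
            for bay in BAYS:
                b = sub[sub["bay"] == bay]
                ax.plot(b["year"], b["trips"] / 1e3, label=bay, lw=1)
            ax.set_title(f"{season} season, ${traj.scenario.cost_per_mile}/mi")
            ax.set_xlabel("year")
            if col == 0:
                ax.set_ylabel("trips (thousands)")
    axes[0][0].legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
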