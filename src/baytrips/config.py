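"""Study constants: bay ordering, seasons, and the calibration tables.

The seven major Texas bays are indexed in coastal order from northeast to
southwest; all spatial neighbour relationships (the banded process-noise
loadings) derive from this ordering.  The base effort/landings table holds the
2009-2010 Texas Parks and Wildlife private-boat trip counts and landings used
to calibrate the representative angler, and the choice coefficients are the
conditional-logit estimates for distance and expected catch of the two target
species (red drum, spotted seatrout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Bay codes in coastal order (Galveston ... Lower Laguna Madre).
BAYS: tuple[str, ...] = ("GL", "MG", "SA", "AR", "CC", "UL", "LL")

BAY_NAMES: dict[str, str] = {
    "GL": "Galveston",
    "MG": "Matagorda",
    "SA": "San Antonio",
    "AR": "Aransas",
    "CC": "Corpus Christi",
    "UL": "Upper Laguna Madre",
    "LL": "Lower Laguna Madre",
}

N_BAYS = len(BAYS)

#: Monitoring seasons (gillnet sampling), in within-year order.
SEASONS: tuple[str, ...] = ("spring", "fall")
#: Fishing seasons fed by the monitoring seasons (spring -> high, fall -> low).
FISHING_SEASONS: tuple[str, ...] = ("high", "low")

SPECIES: tuple[str, ...] = ("red_drum", "spotted_seatrout")

#: Days in the high (summer) and low (winter) fishing seasons.
SEASON_DAYS: dict[str, int] = {"high": 189, "low": 176}

#: Average days fished per year by a Texas saltwater angler (2004 survey).
ANNUAL_FISHING_DAYS = 20.0

#: Willingness to pay for a fishing day, $ (calibration constant).
WTP_PER_TRIP = 30.0

#: Study years of the monitoring panel.
YEARS: tuple[int, int] = (1982, 2016)


@dataclass(frozen=True)
class ChoiceCoefficients:
    """Conditional-logit utility coefficients.

    beta_d is utility per one-way mile (negative), beta_cR and beta_cS are
    utility per expected fish per trip for red drum and spotted seatrout.
    """

    beta_d: float
    beta_cR: float
    beta_cS: float
    se_d: float | None = None
    se_cR: float | None = None
    se_cS: float | None = None

    def __post_init__(self) -> None:
        if not self.beta_d < 0:
            raise ValueError("beta_d must be negative (distance is a cost)")

    def beta_c(self, species: str) -> float:
        if species == "red_drum":
            return self.beta_cR
        if species == "spotted_seatrout":
            return self.beta_cS
        raise KeyError(f"unknown species {species!r}")


#: Published estimates for the Gulf day-trip anglers (distance in miles).
STUDY_CHOICE_COEFFICIENTS = ChoiceCoefficients(
    beta_d=-0.082, beta_cR=0.170, beta_cS=0.347,
    se_d=0.001, se_cR=0.028, se_cS=0.013,
)


@dataclass(frozen=True)
class BaseSeasonTable:
    """Per-bay base trips and landings for one fishing season.

    trips are private-boat trips per season, harvest_* are fish landed per
    season, both in coastal bay order.
    """

    season: str
    trips: np.ndarray
    harvest_red_drum: np.ndarray
    harvest_spotted_seatrout: np.ndarray

    def __post_init__(self) -> None:
        if self.season not in FISHING_SEASONS:
            raise ValueError(f"season must be one of {FISHING_SEASONS}")
        for name in ("trips", "harvest_red_drum", "harvest_spotted_seatrout"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (N_BAYS,):
                raise ValueError(f"{name} must have {N_BAYS} entries")
        if not np.all(self.trips > 0):
            raise ValueError("trips must be strictly positive")
        if np.any(self.harvest_red_drum < 0) or np.any(self.harvest_spotted_seatrout < 0):
            raise ValueError("harvests must be non-negative")

    def harvest(self, species: str) -> np.ndarray:
        if species == "red_drum":
            return self.harvest_red_drum
        if species == "spotted_seatrout":
            return self.harvest_spotted_seatrout
        raise KeyError(f"unknown species {species!r}")


#: 2009-2010 base effort and landings (trips and fish per season per bay),
#: coastal order GL, MG, SA, AR, CC, UL, LL.
BASE_HIGH = BaseSeasonTable(
    season="high",
    trips=np.array([191165, 75973, 57864, 92666, 62542, 83636, 68104], float),
    harvest_red_drum=np.array(
        [30997, 13471, 14321, 14930, 13898, 19488, 17097], float),
    harvest_spotted_seatrout=np.array(
        [104042, 54118, 28796, 20811, 20298, 76372, 56830], float),
)

BASE_LOW = BaseSeasonTable(
    season="low",
    trips=np.array([50761, 29020, 19232, 52620, 35516, 40916, 33185], float),
    harvest_red_drum=np.array(
        [7243, 5575, 5035, 8461, 5655, 4143, 6050], float),
    harvest_spotted_seatrout=np.array(
        [17865, 10406, 12892, 16045, 6746, 18537, 15154], float),
)

BASE_TABLES: dict[str, BaseSeasonTable] = {"high": BASE_HIGH, "low": BASE_LOW}


@dataclass(frozen=True)
class CatchWeights:
    """Weights of the expected-catch smoother.

    distance_decay is the per-mile geometric decline rate of the weight given
    to catch observed at other sites; wave_weight discounts observations from
    the previous two-month wave in the same year; year_weight discounts the
    same wave one year earlier.
    """

    distance_decay: float
    wave_weight: float
    year_weight: float

    def __post_init__(self) -> None:
        for name in ("distance_decay", "wave_weight", "year_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


#: Published smoothing weights per species.
STUDY_CATCH_WEIGHTS: dict[str, CatchWeights] = {
    "red_drum": CatchWeights(distance_decay=0.01, wave_weight=0.54, year_weight=0.0),
    "spotted_seatrout": CatchWeights(distance_decay=0.08, wave_weight=0.35, year_weight=0.84),
}
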