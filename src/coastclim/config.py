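"""Configuration objects for the synthetic study system and the pipeline.

The synthetic configuration plays two roles: it parameterises the data
generators (surveys, gridded ensembles, population density) and it records
the "truth" those generators embed, so recovery experiments can compare
pipeline output against known generating values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

#: Occupation categories recorded on the survey instrument.
OCCUPATIONS = (
    "farming",
    "cash_crop",
    "fishing",
    "mariculture",
    "gleaning",
    "fish_trading",
    "salaried",
    "informal",
    "tourism",
    "other",
)

#: Number of material items on the asset checklist.
N_ITEMS = 16

HISTORICAL_WINDOW = (1983, 2013)
FUTURE_WINDOW = (2046, 2056)

SCENARIOS = ("ssp126", "ssp585")

CROPS = ("rice", "maize", "cassava")

#: Fisheries ensemble: 9 ecosystem models, two of which were forced by a
#: single Earth-system model, giving 16 runs in total.
FISHERY_MODELS_TWO_ESM = (
    "BOATS", "DBEM", "EcoOcean", "EcoTroph", "FEISTY", "Macroecological", "ZooMSS",
)
FISHERY_MODELS_ONE_ESM = ("APECOSM", "DBPM")
FISHERY_ESMS = ("GFDL-ESM4", "IPSL-CM6A-LR")

#: Crop ensemble: 4 crop models x 5 ESM forcings = 20 runs; cassava yields
#: exist only for the LPJmL family.
CROP_MODELS = ("EPIC-IIASA", "LPJmL", "pDSSAT", "PEPIC")
CROP_ESMS = (
    "GFDL-ESM4", "IPSL-CM6A-LR", "MPI-ESM1-2-HR", "MRI-ESM2-0", "UKESM1-0-LL",
)
CASSAVA_MODELS = ("LPJmL",)


def fishery_run_names() -> list[str]:
    names = [f"{m}_{e}" for m in FISHERY_MODELS_TWO_ESM for e in FISHERY_ESMS]
    names += [f"{m}_IPSL-CM6A-LR" for m in FISHERY_MODELS_ONE_ESM]
    return names


def crop_run_names() -> list[str]:
    return [f"{m}_{e}" for m in CROP_MODELS for e in CROP_ESMS]


@dataclass
class ScenarioTruth:
    """Generating values for one emissions scenario.

    Percent changes are mid-century relative to the historical window.
    ``regional_sd`` controls a smooth between-site anomaly field (shared by
    all runs of a sector), ``run_sd`` the run-to-run offsets, and
    ``cell_noise_sd`` i.i.d. per-cell noise.
    """

    fisheries_mean: float
    crop_means: dict[str, float]
    run_sd: float = 5.0
    cell_noise_sd: float = 10.0
    regional_sd: float = 10.0
    crop_regional_sd: float = 8.0
    regional_scale_deg: float = 6.0


@dataclass
class GridSpec:
    lon_min: float = 100.0
    lon_max: float = 130.0
    lat_min: float = -15.0
    lat_max: float = 15.0
    ocean_res: float = 1.0
    crop_res: float = 0.5

    def __post_init__(self) -> None:
        for res in (self.ocean_res, self.crop_res):
            nlon = (self.lon_max - self.lon_min) / res
            nlat = (self.lat_max - self.lat_min) / res
            if abs(nlon - round(nlon)) > 1e-9 or abs(nlat - round(nlat)) > 1e-9:
                raise ValueError(
                    f"resolution {res} does not divide the bounding box"
                )


@dataclass
class WealthModel:
    """Latent-wealth model behind the 16 binary material items.

    Each household draws a latent wealth w ~ N(country mean, sd); item j is
    present with probability logistic(intercept_j + slope_j * w).
    """

    country_means: tuple[float, ...]
    country_sd: float = 1.0
    item_slopes: tuple[float, ...] = tuple(
        [0.8 + 0.05 * j for j in range(N_ITEMS)]
    )
    item_intercepts: tuple[float, ...] = tuple(
        [-1.5 + 0.2 * j for j in range(N_ITEMS)]
    )

    def __post_init__(self) -> None:
        if len(self.item_slopes) != N_ITEMS or len(self.item_intercepts) != N_ITEMS:
            raise ValueError(f"wealth model requires {N_ITEMS} item loadings")


@dataclass
class SyntheticConfig:
    """Full parameterisation of the synthetic study system.

    ``sector_engagement_probs`` gives, per country, the probability that a
    household engages in (agriculture only, fisheries only, both, neither
    primary sector).  ``rank_preference`` is the probability that, in a
    dual-sector household, the best fisheries occupation outranks the best
    agriculture occupation.  ``wealth_dependence_tilt`` shifts the log-odds
    of natural-resource engagement per unit of community latent wealth
    (negative: wealthier communities depend less on the two sectors).
    """

    seed: int = 0
    n_countries: int = 5
    communities_per_country: Sequence[int] = (15, 15, 14, 14, 14)
    households_range: tuple[int, int] = (13, 150)
    sector_engagement_probs: Sequence[tuple[float, float, float, float]] = (
        (0.25, 0.25, 0.35, 0.15),
        (0.20, 0.30, 0.35, 0.15),
        (0.25, 0.30, 0.30, 0.15),
        (0.15, 0.35, 0.35, 0.15),
        (0.20, 0.25, 0.40, 0.15),
    )
    rank_preference: float = 0.6
    p_off_occupation: float = 0.5
    wealth_model: WealthModel | None = None
    wealth_dependence_tilt: float = -0.5
    grid: GridSpec = field(default_factory=GridSpec)
    scenario_truth: dict[str, ScenarioTruth] = field(default_factory=dict)
    historical_window: tuple[int, int] = HISTORICAL_WINDOW
    future_window: tuple[int, int] = FUTURE_WINDOW
    historical_level_ocean: float = 100.0
    historical_level_crop: float = 5.0
    population_mean_density: float = 120.0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValueError("need at least one country")
        if len(self.communities_per_country) != self.n_countries:
            raise ValueError(
                "communities_per_country must have one entry per country"
            )
        if any(c < 1 for c in self.communities_per_country):
            raise ValueError("empty community requested")
        lo, hi = self.households_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid households range")
        if len(self.sector_engagement_probs) != self.n_countries:
            raise ValueError("sector probabilities must have one tuple per country")
        for probs in self.sector_engagement_probs:
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError("sector probabilities must lie in [0, 1]")
            if sum(probs) > 1.0 + 1e-9:
                raise ValueError("sector probability tuple sums above 1")
        if not 0.0 <= self.rank_preference <= 1.0:
            raise ValueError("rank_preference must lie in [0, 1]")
        if self.wealth_model is None:
            means = tuple(-0.5 + 0.25 * k for k in range(self.n_countries))
            self.wealth_model = WealthModel(country_means=means)
        if not self.scenario_truth:
            self.scenario_truth = default_scenario_truth()
        h0, h1 = self.historical_window
        f0, f1 = self.future_window
        if h1 >= f0:
            raise ValueError("historical and future windows must be disjoint")
        if self.historical_level_ocean <= 0 or self.historical_level_crop <= 0:
            raise ValueError("historical baseline level must be positive")

    @property
    def n_communities(self) -> int:
        return int(sum(self.communities_per_country))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["grid"] = GridSpec(**raw["grid"])
        raw["wealth_model"] = WealthModel(
            country_means=tuple(raw["wealth_model"]["country_means"]),
            country_sd=raw["wealth_model"]["country_sd"],
            item_slopes=tuple(raw["wealth_model"]["item_slopes"]),
            item_intercepts=tuple(raw["wealth_model"]["item_intercepts"]),
        )
        raw["scenario_truth"] = {
            k: ScenarioTruth(**v) for k, v in raw["scenario_truth"].items()
        }
        for key in (
            "households_range", "historical_window", "future_window",
        ):
            raw[key] = tuple(raw[key])
        raw["communities_per_country"] = tuple(raw["communities_per_country"])
        raw["sector_engagement_probs"] = tuple(
            tuple(t) for t in raw["sector_engagement_probs"]
        )
        return cls(**raw)


def default_scenario_truth() -> dict[str, ScenarioTruth]:
    """Generating truths for the two emissions scenarios.

    The harsh scenario embeds a ~15-point mean fisheries loss against a small
    mean agricultural gain driven by rice, the mild scenario a muted version
    of both; between-site spread comes from the smooth regional anomaly
    fields.
    """
    return {
        "ssp126": ScenarioTruth(
            fisheries_mean=-5.0,
            crop_means={"rice": 3.6, "maize": -0.5, "cassava": -0.5},
        ),
        "ssp585": ScenarioTruth(
            fisheries_mean=-15.0,
            crop_means={"rice": 9.6, "maize": -3.0, "cassava": -3.0},
        ),
    }


@dataclass
class PipelineConfig:
    """Paths and parameters for an end-to-end run."""

    output_dir: str = "results"
    survey_long_csv: str | None = None
    survey_items_csv: str | None = None
    grids_dir: str | None = None
    population_nc: str | None = None
    sites_csv: str | None = None
    scenarios: tuple[str, ...] = SCENARIOS
    n_ocean_cells: int = 20
    land_window: int = 11
    n_boot: int = 1000
    seed: int = 0
    synthetic: SyntheticConfig | None = None

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("synthetic") is not None:
            syn = raw["synthetic"]
            syn["grid"] = GridSpec(**syn["grid"])
            syn["wealth_model"] = WealthModel(
                country_means=tuple(syn["wealth_model"]["country_means"]),
                country_sd=syn["wealth_model"]["country_sd"],
                item_slopes=tuple(syn["wealth_model"]["item_slopes"]),
                item_intercepts=tuple(syn["wealth_model"]["item_intercepts"]),
            )
            syn["scenario_truth"] = {
                k: ScenarioTruth(**v) for k, v in syn["scenario_truth"].items()
            }
            for key in ("households_range", "historical_window", "future_window"):
                syn[key] = tuple(syn[key])
            syn["communities_per_country"] = tuple(syn["communities_per_country"])
            syn["sector_engagement_probs"] = tuple(
                tuple(t) for t in syn["sector_engagement_probs"]
            )
            raw["synthetic"] = SyntheticConfig(**syn)
        if raw.get("scenarios") is not None:
            raw["scenarios"] = tuple(raw["scenarios"])
        return cls(**raw)
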