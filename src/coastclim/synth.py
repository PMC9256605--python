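"""Synthetic study-system generators.

Emulates the inputs of the community climate potential-impact analysis:

* household livelihood surveys (ranked occupations + 16 binary material
  items) across countries and communities,
* gridded multi-model ensembles of ocean total-consumer biomass (1 degree)
  and rain-fed crop yields (0.5 degree) for a historical window and two
  mid-century emissions scenarios,
* a coastal population-density grid, and
* community site coordinates on the synthetic coastline.

Every generator draws from its own child stream of the master seed, spawned
in a fixed order (survey, fisheries grids, crop grids, population, sites),
so adding draws to one generator never shifts another.  The generating
"truth" (per-site true change, per-community engagement probabilities,
latent wealth) is returned alongside the data and is never consumed by
pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .config import (
    CROPS,
    CASSAVA_MODELS,
    CROP_ESMS,
    N_ITEMS,
    SyntheticConfig,
    crop_run_names,
    fishery_run_names,
)

FISHERIES_OCCS = ("fishing", "mariculture", "gleaning", "fish_trading")
AGRICULTURE_OCCS = ("farming", "cash_crop")
OFF_OCCS = ("salaried", "informal", "tourism", "other")

_STREAMS = {"survey": 0, "fishery": 1, "crop": 2, "population": 3, "sites": 4}


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class SyntheticTruth:
    """Generating values stored alongside synthetic outputs (audit only)."""

    community_probs: pd.DataFrame = field(default_factory=pd.DataFrame)
    household_wealth: pd.DataFrame = field(default_factory=pd.DataFrame)
    site_true_change: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path) -> None:
        payload = {
            "community_probs": self.community_probs.to_dict(orient="list"),
            "household_wealth": self.household_wealth.to_dict(orient="list"),
            "site_true_change": self.site_true_change.to_dict(orient="list"),
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# coastline geometry (shared by both grid resolutions)
# ---------------------------------------------------------------------------

def coast_lon(lat: np.ndarray | float) -> np.ndarray | float:
    """Longitude of the synthetic coastline at a given latitude.

    Land lies east of this curve, ocean west.  Deterministic, so the 1 and
    0.5 degree masks are mutually consistent.
    """
    return 115.0 + 5.0 * np.sin(np.asarray(lat, dtype=float) * np.pi / 15.0)


def grid_coords(config: SyntheticConfig, res: float):
    g = config.grid
    lats = np.arange(g.lat_min + res / 2, g.lat_max, res)
    lons = np.arange(g.lon_min + res / 2, g.lon_max, res)
    return lats, lons


def land_mask(config: SyntheticConfig, res: float) -> xr.DataArray:
    """1 = land, 0 = ocean on the grid of the given resolution."""
    lats, lons = grid_coords(config, res)
    mask = (lons[None, :] > np.asarray(coast_lon(lats))[:, None]).astype(np.int8)
    return xr.DataArray(mask, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"))


def coastal_flags(mask: xr.DataArray) -> xr.DataArray:
    """Land cells with at least one ocean cell among their 8 neighbours."""
    m = mask.values.astype(bool)
    ocean_adjacent = np.zeros_like(m)
    padded = np.pad(~m, 1, constant_values=False)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            ocean_adjacent |= padded[1 + di : 1 + di + m.shape[0],
                                     1 + dj : 1 + dj + m.shape[1]]
    return xr.DataArray(
        (m & ocean_adjacent), coords=mask.coords, dims=mask.dims
    )


# ---------------------------------------------------------------------------
# survey generation
# ---------------------------------------------------------------------------

def _tilted_probs(base: tuple[float, float, float, float], tilt: float,
                  community_wealth: float) -> np.ndarray:
    """Shift sector-engagement odds by community wealth.

    The odds of each resource-engaged category (agriculture only, fisheries
    only, both) against 'neither' are multiplied by exp(tilt * wealth).
    """
    p = np.asarray(base, dtype=float)
    w = np.exp(tilt * community_wealth)
    out = p.copy()
    out[:3] *= w
    total = out.sum()
    return out / total


def generate_survey(config: SyntheticConfig):
    """Generate household survey tables.

    Returns ``(long, items, truth)``: a long table with one row per ranked
    occupation (community_id, country, household_id, occupation_category,
    rank), a wide table of 16 binary item columns per household, and the
    generating truth.
    """
    rng = _rng(config, "survey")
    wm = config.wealth_model
    rows = []
    item_rows = []
    truth_comm = []
    truth_house = []
    slopes = np.asarray(wm.item_slopes)
    intercepts = np.asarray(wm.item_intercepts)

    for ci in range(config.n_countries):
        country = f"country_{ci}"
        for cj in range(config.communities_per_country[ci]):
            community = f"{country}_comm_{cj}"
            comm_wealth = wm.country_means[ci] + rng.normal(0.0, 0.5)
            probs = _tilted_probs(
                config.sector_engagement_probs[ci],
                config.wealth_dependence_tilt,
                comm_wealth,
            )
            n_house = int(rng.integers(*config.households_range, endpoint=True))
            truth_comm.append(
                {
                    "community_id": community,
                    "country": country,
                    "wealth_mean": comm_wealth,
                    "p_ag_only": probs[0],
                    "p_fish_only": probs[1],
                    "p_both": probs[2],
                    "p_neither": probs[3],
                }
            )
            for hh in range(n_house):
                household = f"{community}_h{hh}"
                wealth = rng.normal(comm_wealth, wm.country_sd)
                cat = rng.choice(4, p=probs)
                occs: list[str] = []
                if cat in (0, 2):  # agriculture
                    n_ag = 1 + int(rng.random() < 0.3)
                    occs += list(rng.choice(AGRICULTURE_OCCS, size=n_ag,
                                            replace=False))
                if cat in (1, 2):  # fisheries
                    n_f = 1 + int(rng.random() < 0.4)
                    occs += list(rng.choice(FISHERIES_OCCS, size=n_f,
                                            replace=False))
                if cat == 3 or rng.random() < config.p_off_occupation:
                    occs += [str(rng.choice(OFF_OCCS))]
                ranks = list(rng.permutation(len(occs)) + 1)
                if cat == 2:
                    ranks = _orient_ranks(
                        occs, ranks,
                        fisheries_first=rng.random() < config.rank_preference,
                    )
                for occ, rank in zip(occs, ranks):
                    rows.append(
                        {
                            "community_id": community,
                            "country": country,
                            "household_id": household,
                            "occupation_category": occ,
                            "rank": int(rank),
                        }
                    )
                p_items = 1.0 / (1.0 + np.exp(-(intercepts + slopes * wealth)))
                items = (rng.random(N_ITEMS) < p_items).astype(int)
                item_rows.append(
                    {
                        "community_id": community,
                        "country": country,
                        "household_id": household,
                        **{f"item_{j:02d}": int(v) for j, v in enumerate(items)},
                    }
                )
                truth_house.append(
                    {"household_id": household, "latent_wealth": wealth}
                )

    long = pd.DataFrame(rows)
    items = pd.DataFrame(item_rows)
    truth = SyntheticTruth(
        community_probs=pd.DataFrame(truth_comm),
        household_wealth=pd.DataFrame(truth_house),
    )
    return long, items, truth


def _orient_ranks(occs: list[str], ranks: list[int], fisheries_first: bool):
    """Swap ranks so the best fisheries occupation out- or under-ranks the
    best agriculture occupation as requested (rank 1 = most important)."""
    fish_idx = [i for i, o in enumerate(occs) if o in FISHERIES_OCCS]
    ag_idx = [i for i, o in enumerate(occs) if o in AGRICULTURE_OCCS]
    if not fish_idx or not ag_idx:
        return ranks
    best_f = min(fish_idx, key=lambda i: ranks[i])
    best_a = min(ag_idx, key=lambda i: ranks[i])
    fish_wins = ranks[best_f] < ranks[best_a]
    if fish_wins != fisheries_first:
        ranks = list(ranks)
        ranks[best_f], ranks[best_a] = ranks[best_a], ranks[best_f]
    return ranks


# ---------------------------------------------------------------------------
# gridded ensembles
# ---------------------------------------------------------------------------

def _regional_field(rng, lats, lons, sd: float, scale_deg: float) -> np.ndarray:
    """Smooth anomaly field: coarse-grid white noise, bilinearly interpolated.

    Shared by all runs of a sector; this is what makes sites genuinely
    differ in their true exposure.
    """
    if sd == 0:
        return np.zeros((len(lats), len(lons)))
    pad = scale_deg
    clat = np.arange(lats[0] - pad, lats[-1] + pad + scale_deg, scale_deg)
    clon = np.arange(lons[0] - pad, lons[-1] + pad + scale_deg, scale_deg)
    coarse = rng.normal(0.0, sd, size=(len(clat), len(clon)))
    interp = RegularGridInterpolator((clat, clon), coarse, method="linear")
    pts = np.stack(np.meshgrid(lats, lons, indexing="ij"), axis=-1)
    return interp(pts.reshape(-1, 2)).reshape(len(lats), len(lons))


def _spatial_texture(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Deterministic multiplicative texture so baseline fields are not flat."""
    la, lo = np.meshgrid(lats, lons, indexing="ij")
    return 1.0 + 0.3 * np.sin(la * 0.7) * np.cos(lo * 0.5)


def _build_ensemble(
    rng: np.random.Generator,
    config: SyntheticConfig,
    run_names: list[str],
    res: float,
    base_level: float,
    true_mean: float,
    run_sd: float,
    cell_sd: float,
    regional_sd: float,
    regional_scale: float,
    scenario: str,
    units: str,
    regional: np.ndarray | None = None,
) -> tuple[xr.Dataset, np.ndarray]:
    if base_level <= 0:
        raise ValueError("historical baseline level must be positive")
    lats, lons = grid_coords(config, res)
    mask = land_mask(config, res)
    h0, h1 = config.historical_window
    f0, f1 = config.future_window
    years = np.concatenate(
        [np.arange(h0, h1 + 1), np.arange(f0, f1 + 1)]
    )
    n_hist = h1 - h0 + 1
    n_runs = len(run_names)
    hist_field = base_level * _spatial_texture(lats, lons)

    if regional is None:
        regional = _regional_field(rng, lats, lons, regional_sd, regional_scale)
    run_offsets = rng.normal(0.0, run_sd, size=n_runs) if run_sd > 0 else np.zeros(n_runs)
    cell_noise = (
        rng.normal(0.0, cell_sd, size=(n_runs, len(lats), len(lons)))
        if cell_sd > 0
        else np.zeros((n_runs, len(lats), len(lons)))
    )
    # future = historical x (1 + true change), change in percent
    change = (
        true_mean
        + regional[None, :, :]
        + run_offsets[:, None, None]
        + cell_noise
    )
    values = np.empty((n_runs, len(years), len(lats), len(lons)))
    values[:, :n_hist] = hist_field[None, None, :, :]
    values[:, n_hist:] = (
        hist_field[None, None, :, :] * (1.0 + change[:, None, :, :] / 100.0)
    )
    ds = xr.Dataset(
        {
            "value": (
                ("run", "year", "lat", "lon"),
                values,
                {"units": units},
            ),
            "mask": (
                ("lat", "lon"),
                mask.values,
                {"long_name": "land-sea mask", "flag_meanings": "1=land 0=ocean"},
            ),
        },
        coords={
            "run": run_names,
            "year": years,
            "lat": ("lat", lats, {"units": "degrees_north"}),
            "lon": ("lon", lons, {"units": "degrees_east"}),
        },
        attrs={"scenario": scenario, "Conventions": "CF-1.8"},
    )
    return ds, regional


def generate_grids(config: SyntheticConfig) -> dict[str, dict[str, xr.Dataset]]:
    """Build the per-scenario ensembles.

    Returns ``{"fisheries": {scenario: Dataset}, "rice": ..., "maize": ...,
    "cassava": ...}``.  The fisheries ensemble has 16 runs on the 1 degree
    grid; each crop has the 4 model x 5 ESM runs on the 0.5 degree grid,
    except cassava which comes from the single-model (LPJmL) family.
    Per-scenario true regional-change fields are stored in each dataset's
    ``true_change`` variable for recovery experiments (audit only).
    """
    out: dict[str, dict[str, xr.Dataset]] = {}
    f_rng = _rng(config, "fishery")
    c_rng = _rng(config, "crop")
    # One unit-variance spatial response pattern per sector, shared across
    # scenarios and scaled by each scenario's regional SD: scenario
    # severity amplifies a common pattern, so a site losing under the mild
    # scenario also loses under the harsh one (as in forcing-scaled
    # projections).  Patterns are drawn before any scenario-level noise so
    # adding scenarios does not shift them.
    scale_deg = next(iter(config.scenario_truth.values())).regional_scale_deg
    o_lats, o_lons = grid_coords(config, config.grid.ocean_res)
    crop_lats, crop_lons = grid_coords(config, config.grid.crop_res)
    pattern_f = _regional_field(f_rng, o_lats, o_lons, 1.0, scale_deg)
    pattern_c = _regional_field(c_rng, crop_lats, crop_lons, 1.0, scale_deg)
    out["fisheries"] = {}
    for scenario in sorted(config.scenario_truth):
        truth = config.scenario_truth[scenario]
        regional = truth.regional_sd * pattern_f
        ds, _ = _build_ensemble(
            f_rng, config, fishery_run_names(), config.grid.ocean_res,
            config.historical_level_ocean, truth.fisheries_mean,
            truth.run_sd, truth.cell_noise_sd, truth.regional_sd,
            truth.regional_scale_deg, scenario, "g m-2",
            regional=regional,
        )
        ds["true_change"] = (("lat", "lon"), truth.fisheries_mean + regional)
        out["fisheries"][scenario] = ds
    for scenario in sorted(config.scenario_truth):
        truth = config.scenario_truth[scenario]
        regional = truth.crop_regional_sd * pattern_c
        for crop in CROPS:
            out.setdefault(crop, {})
            runs = (
                [f"{m}_{e}" for m in CASSAVA_MODELS for e in CROP_ESMS]
                if crop == "cassava"
                else crop_run_names()
            )
            ds, _ = _build_ensemble(
                c_rng, config, runs, config.grid.crop_res,
                config.historical_level_crop, truth.crop_means[crop],
                truth.run_sd, truth.cell_noise_sd, truth.crop_regional_sd,
                truth.regional_scale_deg, scenario, "t ha-1",
                regional=regional,
            )
            ds["true_change"] = (
                ("lat", "lon"), truth.crop_means[crop] + regional
            )
            out[crop][scenario] = ds
    return out


# ---------------------------------------------------------------------------
# population grid and sites
# ---------------------------------------------------------------------------

def generate_population_grid(config: SyntheticConfig) -> xr.Dataset:
    """Population density (people per km2) on the 0.5 degree grid.

    Density is positive on land (lognormal around the configured mean) and
    zero on ocean; ``coastal`` flags land cells adjacent to ocean.
    """
    rng = _rng(config, "population")
    mask = land_mask(config, config.grid.crop_res)
    mu = np.log(config.population_mean_density) - 0.5
    density = np.where(
        mask.values == 1,
        rng.lognormal(mean=mu, sigma=1.0, size=mask.shape),
        0.0,
    )
    coast = coastal_flags(mask)
    return xr.Dataset(
        {
            "density": (("lat", "lon"), density, {"units": "km-2"}),
            "mask": (("lat", "lon"), mask.values),
            "coastal": (("lat", "lon"), coast.values.astype(np.int8)),
        },
        coords=mask.coords,
    )


def place_sites(config: SyntheticConfig) -> pd.DataFrame:
    """Put one site per community on coastal land cells of the fine grid.

    Sites are spread evenly along the coastline (sorted by latitude) and
    countries occupy contiguous blocks, so country becomes a real spatial
    grouping for the regional anomaly fields.
    """
    mask = land_mask(config, config.grid.crop_res)
    coast = coastal_flags(mask)
    ii, jj = np.nonzero(coast.values)
    if len(ii) == 0:
        raise ValueError("no coastal land cells in the bounding box")
    lats = coast["lat"].values[ii]
    lons = coast["lon"].values[jj]
    order = np.lexsort((lons, lats))
    lats, lons = lats[order], lons[order]
    n = config.n_communities
    if len(lats) < n:
        # reuse cells if the coastline is shorter than the community list
        reps = int(np.ceil(n / len(lats)))
        lats = np.tile(lats, reps)
        lons = np.tile(lons, reps)
    idx = np.linspace(0, len(lats) - 1, n).round().astype(int)
    recs = []
    k = 0
    for ci in range(config.n_countries):
        country = f"country_{ci}"
        for cj in range(config.communities_per_country[ci]):
            recs.append(
                {
                    "community_id": f"{country}_comm_{cj}",
                    "country": country,
                    "lat": float(lats[idx[k]]),
                    "lon": float(lons[idx[k]]),
                }
            )
            k += 1
    return pd.DataFrame(recs)
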