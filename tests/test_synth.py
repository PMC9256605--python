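"""Synthetic-data generators: determinism, degenerate settings, marginals,
noise-free truth, and coastal adjacency."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from dataclasses import replace

from coastclim import synth
from coastclim.config import GridSpec, ScenarioTruth, SyntheticConfig
from coastclim.survey_metrics import community_sensitivity


def _noise_free(truth_pct: float, crop_pct: float = 0.0) -> dict:
    return {
        "ssp585": ScenarioTruth(
            fisheries_mean=truth_pct,
            crop_means={c: crop_pct for c in ("rice", "maize", "cassava")},
            run_sd=0.0, cell_noise_sd=0.0, regional_sd=0.0,
            crop_regional_sd=0.0,
        )
    }


class TestSurvey:
    def test_same_seed_identical_tables(self, tiny_config):
        l1, i1, _ = synth.generate_survey(tiny_config)
        l2, i2, _ = synth.generate_survey(tiny_config)
        pd.testing.assert_frame_equal(l1, l2)
        pd.testing.assert_frame_equal(i1, i2)

    def test_different_seed_differs(self, tiny_config):
        l1, _, _ = synth.generate_survey(tiny_config)
        l2, _, _ = synth.generate_survey(replace(tiny_config, seed=8))
        assert not l1.equals(l2)

    def test_every_household_has_distinct_ranked_occupations(self, tiny_config):
        long, _, _ = synth.generate_survey(tiny_config)
        for _, grp in long.groupby("household_id"):
            ranks = sorted(grp["rank"])
            assert ranks == list(range(1, len(ranks) + 1))

    def test_degenerate_dual_sector_ranking(self, tiny_config):
        cfg = replace(
            tiny_config,
            sector_engagement_probs=((0.0, 0.0, 1.0, 0.0),) * 2,
            rank_preference=1.0,
        )
        long, _, _ = synth.generate_survey(cfg)
        fish = {"fishing", "mariculture", "gleaning", "fish_trading"}
        ag = {"farming", "cash_crop"}
        for _, grp in long.groupby("household_id"):
            best = grp.groupby(
                grp["occupation_category"].map(
                    lambda o: "f" if o in fish else ("a" if o in ag else "o")
                )
            )["rank"].min()
            assert best["f"] < best["a"]

    def test_all_off_sector_forces_zero_sensitivity(self, tiny_config):
        cfg = replace(
            tiny_config, sector_engagement_probs=((0.0, 0.0, 0.0, 1.0),) * 2
        )
        long, _, _ = synth.generate_survey(cfg)
        sens = community_sensitivity(long)
        assert (sens[["S_A", "S_F", "S_AF"]] == 0).all().all()

    def test_empty_community_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="empty community"):
            replace(tiny_config, communities_per_country=(0, 6))

    def test_marginals_converge_to_configured_probabilities(self):
        """Realised sector engagement matches the configured multinomial at
        n=5000 within 3 binomial SE (wealth tilt disabled)."""
        probs = (0.3, 0.2, 0.35, 0.15)
        cfg = SyntheticConfig(
            seed=11, n_countries=1, communities_per_country=(1,),
            households_range=(5000, 5000),
            sector_engagement_probs=(probs,),
            wealth_dependence_tilt=0.0,
            grid=GridSpec(lon_min=110, lon_max=120, lat_min=-5, lat_max=5),
        )
        # suppress the community-level wealth offset via tilt=0 (probs untouched)
        long, _, truth = synth.generate_survey(cfg)
        fish = {"fishing", "mariculture", "gleaning", "fish_trading"}
        ag = {"farming", "cash_crop"}
        n = long["household_id"].nunique()
        assert n == 5000
        cats = []
        for _, grp in long.groupby("household_id"):
            has_f = grp["occupation_category"].isin(fish).any()
            has_a = grp["occupation_category"].isin(ag).any()
            cats.append((has_a, has_f))
        realised = {
            "ag_only": np.mean([a and not f for a, f in cats]),
            "fish_only": np.mean([f and not a for a, f in cats]),
            "both": np.mean([a and f for a, f in cats]),
            "neither": np.mean([not a and not f for a, f in cats]),
        }
        for p, (label, obs) in zip(probs, realised.items()):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) <= 3 * se, (label, obs, p)


class TestGrids:
    def test_noise_free_exact_change(self, tiny_config):
        cfg = replace(tiny_config, scenario_truth=_noise_free(-20.0))
        grids = synth.generate_grids(cfg)
        ds = grids["fisheries"]["ssp585"]
        years = ds["year"].values
        hist = ds["value"].values[:, years <= 2013]
        fut = ds["value"].values[:, years >= 2046]
        change = 100 * (fut.mean(axis=1) - hist.mean(axis=1)) / hist.mean(axis=1)
        assert np.allclose(change, -20.0, atol=1e-10)

    def test_null_change_has_near_zero_ensemble_mean(self, tiny_config):
        truth = {
            "ssp585": ScenarioTruth(
                fisheries_mean=0.0,
                crop_means={"rice": 0.0, "maize": 0.0, "cassava": 0.0},
                run_sd=4.0, cell_noise_sd=0.0, regional_sd=0.0,
                crop_regional_sd=0.0,
            )
        }
        cfg = replace(tiny_config, scenario_truth=truth)
        ds = synth.generate_grids(cfg)["fisheries"]["ssp585"]
        years = ds["year"].values
        hist = ds["value"].values[:, years <= 2013].mean(axis=1)
        fut = ds["value"].values[:, years >= 2046].mean(axis=1)
        change = 100 * (fut - hist) / hist
        # 16 runs at SD 4 -> SE of ensemble mean = 1
        assert abs(change.mean()) < 3.0

    def test_run_mean_sampling_distribution(self, tiny_config):
        """Ensemble-mean change is an unbiased estimate of the configured
        truth: mean over seeds within 3 SE (run SD 5, 16 runs)."""
        means = []
        for k in range(20):
            truth = {
                "ssp585": ScenarioTruth(
                    fisheries_mean=-15.0,
                    crop_means={"rice": 0, "maize": 0, "cassava": 0},
                    run_sd=5.0, cell_noise_sd=0.0, regional_sd=0.0,
                    crop_regional_sd=0.0,
                )
            }
            cfg = replace(tiny_config, seed=300 + k, scenario_truth=truth)
            ds = synth.generate_grids(cfg)["fisheries"]["ssp585"]
            years = ds["year"].values
            hist = ds["value"].values[:, years <= 2013].mean(axis=1)
            fut = ds["value"].values[:, years >= 2046].mean(axis=1)
            means.append(float((100 * (fut - hist) / hist).mean()))
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - (-15.0)) <= 3 * se

    def test_cassava_single_model_family(self, tiny_config):
        grids = synth.generate_grids(tiny_config)
        runs = list(grids["cassava"]["ssp585"]["run"].values)
        assert len(runs) == 5
        assert all(str(r).startswith("LPJmL") for r in runs)
        assert len(grids["rice"]["ssp585"]["run"]) == 20
        assert len(grids["fisheries"]["ssp585"]["run"]) == 16

    def test_non_positive_baseline_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="positive"):
            replace(tiny_config, historical_level_ocean=0.0)


class TestPopulationAndSites:
    def test_density_nonnegative_and_zero_on_ocean(self, tiny_config):
        pop = synth.generate_population_grid(tiny_config)
        assert (pop["density"].values >= 0).all()
        assert (pop["density"].values[pop["mask"].values == 0] == 0).all()

    def test_coastal_adjacency_matches_brute_force(self):
        """Checkerboard mask: flags equal a hand-enumerated 8-neighbour
        adjacency oracle."""
        rng = np.random.default_rng(5)
        m = (rng.random((9, 11)) > 0.5).astype(np.int8)
        da = xr.DataArray(
            m, coords={"lat": np.arange(9.0), "lon": np.arange(11.0)},
            dims=("lat", "lon"),
        )
        got = synth.coastal_flags(da).values
        for i in range(9):
            for j in range(11):
                if m[i, j] == 0:
                    assert not got[i, j]
                    continue
                expect = any(
                    0 <= i + di < 9 and 0 <= j + dj < 11 and m[i + di, j + dj] == 0
                    for di in (-1, 0, 1)
                    for dj in (-1, 0, 1)
                    if (di, dj) != (0, 0)
                )
                assert got[i, j] == expect

    def test_all_ocean_box_has_no_sites(self, tiny_config):
        cfg = replace(
            tiny_config,
            grid=GridSpec(lon_min=100, lon_max=106, lat_min=-3, lat_max=3),
        )
        with pytest.raises(ValueError, match="coastal"):
            synth.place_sites(cfg)

    def test_uniform_density_above_threshold(self, tiny_config):
        pop = synth.generate_population_grid(tiny_config)
        pop["density"].values[pop["mask"].values == 1] = 30.0
        coastal = pop["coastal"].values.astype(bool)
        assert (pop["density"].values[coastal] > 25).all()

    def test_sites_on_coastal_land(self, tiny_config):
        sites = synth.place_sites(tiny_config)
        mask = synth.land_mask(tiny_config, tiny_config.grid.crop_res)
        coast = synth.coastal_flags(mask)
        for _, s in sites.iterrows():
            v = coast.sel(lat=s["lat"], lon=s["lon"], method="nearest")
            assert bool(v)

    def test_grid_determinism(self, tiny_config):
        g1 = synth.generate_grids(tiny_config)
        g2 = synth.generate_grids(tiny_config)
        xr.testing.assert_identical(
            g1["fisheries"]["ssp126"], g2["fisheries"]["ssp126"]
        )
        xr.testing.assert_identical(g1["maize"]["ssp585"], g2["maize"]["ssp585"])


class TestConfigValidation:
    def test_probabilities_must_sum_below_one(self, tiny_config):
        with pytest.raises(ValueError, match="sums above 1"):
            replace(
                tiny_config,
                sector_engagement_probs=((0.5, 0.5, 0.5, 0.1),) * 2,
            )

    def test_resolution_must_divide_box(self):
        with pytest.raises(ValueError, match="divide"):
            GridSpec(lon_min=110, lon_max=120.3, lat_min=-5, lat_max=5)

    def test_windows_must_be_disjoint(self, tiny_config):
        with pytest.raises(ValueError, match="disjoint"):
            replace(
                tiny_config,
                historical_window=(1983, 2050), future_window=(2046, 2056),
            )

    def test_yaml_round_trip(self, tiny_config, tmp_path):
        p = tmp_path / "cfg.yaml"
        tiny_config.to_yaml(p)
        back = SyntheticConfig.from_yaml(p)
        assert back == tiny_config
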