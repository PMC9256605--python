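"""Exposure extraction: distances, cell selection, relative change,
ensemble aggregation and composites."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from coastclim.exposure import (
    cell_count_sensitivity,
    composite_exposure,
    crop_composite,
    ensemble_stats,
    haversine,
    run_relative_change,
    select_land_window,
    select_ocean_cells,
    site_exposure,
)
from conftest import make_grid
from _oracles import oracle_nearest_cells


class TestHaversine:
    def test_zero_distance_for_identical_points(self):
        assert haversine(0, 0, 0, 0) == 0.0
        assert haversine(-12.3, 45.6, -12.3, 45.6) == 0.0

    def test_quarter_meridian(self):
        # pole-to-equator along a meridian: pi * R / 2
        assert haversine(0, 0, 90, 0) == pytest.approx(10007.54, abs=0.01)
        assert haversine(0, 0, 0, 90) == pytest.approx(10007.54, abs=0.01)

    def test_one_degree_at_equator(self):
        assert haversine(0, 0, 0, 1) == pytest.approx(111.195, abs=0.001)

    def test_symmetry(self):
        assert haversine(10, 20, -30, 140) == pytest.approx(
            haversine(-30, 140, 10, 20), abs=1e-9
        )

    def test_out_of_range_latitude_rejected(self):
        with pytest.raises(ValueError):
            haversine(91, 0, 0, 0)


def _all_ocean(nlat=8, nlon=8):
    return make_grid(
        np.arange(nlat) + 0.5, np.arange(nlon) + 0.5,
        ["r0", "r1"], 100.0, 100.0,
    )


class TestCellSelection:
    def test_site_at_cell_centre_selects_that_cell(self):
        ds = _all_ocean()
        got = select_ocean_cells(3.5, 4.5, ds, n=1)
        assert (got["lat"].iloc[0], got["lon"].iloc[0]) == (3.5, 4.5)

    def test_matches_exhaustive_sort_oracle(self):
        ds = _all_ocean(10, 12)
        lats = ds["lat"].values
        lons = ds["lon"].values
        la, lo = np.meshgrid(lats, lons, indexing="ij")
        got = select_ocean_cells(4.2, 7.9, ds, n=20)
        want = oracle_nearest_cells(4.2, 7.9, la.ravel(), lo.ravel(), 20)
        np.testing.assert_allclose(
            got[["lat", "lon"]].to_numpy(),
            np.c_[la.ravel()[want], lo.ravel()[want]],
        )

    def test_zero_cells_rejected(self):
        with pytest.raises(ValueError):
            select_ocean_cells(0, 0, _all_ocean(), n=0)

    def test_too_few_ocean_cells_rejected(self):
        ds = _all_ocean(2, 2)
        with pytest.raises(ValueError, match="ocean cells"):
            select_ocean_cells(0, 0, ds, n=20)

    def test_all_land_window_has_full_block(self):
        ds = make_grid(
            np.arange(15) + 0.5, np.arange(15) + 0.5, ["r0"], 1, 1,
            mask=np.ones((15, 15)),
        )
        got = select_land_window(7.5, 7.5, ds, window=11)
        assert len(got) == 121

    def test_one_cell_island(self):
        mask = np.zeros((15, 15))
        mask[7, 7] = 1
        ds = make_grid(
            np.arange(15) + 0.5, np.arange(15) + 0.5, ["r0"], 1, 1, mask=mask
        )
        got = select_land_window(7.5, 7.5, ds, window=11)
        assert len(got) == 1
        assert (got["lat"].iloc[0], got["lon"].iloc[0]) == (7.5, 7.5)

    def test_mixed_mask_matches_brute_force(self):
        rng = np.random.default_rng(9)
        mask = (rng.random((15, 15)) > 0.4).astype(int)
        ds = make_grid(
            np.arange(15) + 0.5, np.arange(15) + 0.5, ["r0"], 1, 1, mask=mask
        )
        got = select_land_window(6.5, 8.5, ds, window=5)
        want = {
            (i + 0.5, j + 0.5)
            for i in range(4, 9)
            for j in range(6, 11)
            if mask[i, j]
        }
        assert set(zip(got["lat"], got["lon"])) == want

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            select_land_window(5, 5, _all_ocean(), window=10)

    def test_windowed_ocean_only_rejected(self):
        ds = _all_ocean()
        with pytest.raises(ValueError, match="land"):
            select_land_window(3.5, 3.5, ds, window=3)


class TestRelativeChange:
    def test_no_change(self):
        ds = make_grid([0.5], [0.5], ["a", "b"], 100.0, 100.0)
        cells = pd.DataFrame({"i": [0], "j": [0]})
        np.testing.assert_allclose(run_relative_change(ds, cells), 0.0)

    def test_uniform_twenty_percent_loss(self):
        ds = make_grid([0.5], [0.5], ["a"], 100.0, 80.0)
        cells = pd.DataFrame({"i": [0], "j": [0]})
        np.testing.assert_allclose(run_relative_change(ds, cells), -20.0)

    def test_two_cell_hand_arithmetic(self):
        """hist (100, 200), future (90, 220): 100*(155-150)/150 = +3.333%."""
        hist = np.array([[[100.0, 200.0]]])
        fut = np.array([[[90.0, 220.0]]])
        ds = make_grid([0.5], [0.5, 1.5], ["a"], hist, fut)
        cells = pd.DataFrame({"i": [0, 0], "j": [0, 1]})
        got = run_relative_change(ds, cells)
        assert got[0] == pytest.approx(100 * (155 - 150) / 150, abs=1e-10)

    def test_zero_baseline_run_flagged_missing(self):
        hist = np.stack([np.full((1, 1), 100.0), np.zeros((1, 1))])
        fut = np.stack([np.full((1, 1), 90.0), np.full((1, 1), 50.0)])
        ds = make_grid([0.5], [0.5], ["ok", "bad"], hist, fut)
        cells = pd.DataFrame({"i": [0], "j": [0]})
        got = run_relative_change(ds, cells)
        assert got[0] == pytest.approx(-10.0)
        assert np.isnan(got[1])

    def test_monthly_fields_annualised_first(self):
        ds = make_grid([0.5], [0.5], ["a"], 100.0, 80.0)
        monthly = ds.expand_dims(month=np.arange(1, 13)).copy(deep=True)
        cells = pd.DataFrame({"i": [0], "j": [0]})
        np.testing.assert_allclose(
            run_relative_change(monthly, cells), -20.0
        )

    def test_missing_window_rejected(self):
        ds = make_grid([0.5], [0.5], ["a"], 100.0, 80.0)
        with pytest.raises(ValueError, match="window"):
            run_relative_change(
                ds, pd.DataFrame({"i": [0], "j": [0]}),
                future_window=(2080, 2090),
            )


class TestEnsembleStats:
    def test_twelve_of_sixteen_negative(self):
        changes = np.array([-5.0] * 12 + [2.0] * 4)
        st = ensemble_stats(changes)
        assert st.mean < 0
        assert st.agreement == pytest.approx(12 / 16)

    def test_unanimous_runs(self):
        st = ensemble_stats(np.full(16, -10.0))
        assert (st.mean, st.p25, st.p75, st.agreement) == (-10, -10, -10, 1.0)

    def test_zero_change_counts_as_agreeing(self):
        st = ensemble_stats(np.array([-4.0, -2.0, 0.0, 2.0]))
        assert st.mean == pytest.approx(-1.0)
        assert st.agreement == pytest.approx(3 / 4)

    def test_percentiles_linear_interpolation(self):
        st = ensemble_stats(np.array([0.0, 1.0, 2.0, 3.0]))
        assert st.p25 == pytest.approx(0.75)
        assert st.p75 == pytest.approx(2.25)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            ensemble_stats(np.array([np.nan, np.nan]))

    def test_missing_runs_reduce_denominator(self):
        st = ensemble_stats(np.array([np.nan, -1.0, -2.0, 1.0]))
        assert st.n_runs == 3
        assert st.agreement == pytest.approx(2 / 3)


class TestComposites:
    def test_unweighted_crop_mean(self):
        assert crop_composite({"rice": 9, "maize": -3, "cassava": -3}) == 1.0

    def test_single_crop_identity(self):
        assert crop_composite({"rice": -7.5}) == -7.5

    def test_degenerate_weights_select_one_crop(self):
        got = crop_composite(
            {"rice": 4.0, "maize": -2.0, "cassava": 1.0},
            weights={"rice": 1, "maize": 0, "cassava": 0},
        )
        assert got == 4.0

    def test_zero_weight_sum_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            crop_composite({"rice": 1.0}, weights={"rice": 0.0})

    @pytest.mark.parametrize(
        "ea, ef, want", [(10, -20, -5), (0, 0, 0), (-14.7, 1.2, -6.75)]
    )
    def test_composite_exposure(self, ea, ef, want):
        assert composite_exposure(ea, ef) == pytest.approx(want)

    def test_composite_linearity(self):
        assert composite_exposure(2 * 3.0, 2 * -8.0) == pytest.approx(
            2 * composite_exposure(3.0, -8.0)
        )


class TestTranslationConsistency:
    def test_longitude_shift_leaves_outputs_unchanged(self):
        rng = np.random.default_rng(12)
        nlat, nlon = 12, 12
        mask = np.zeros((nlat, nlon))
        mask[:, 6:] = 1  # east half land
        hist = rng.uniform(50, 150, size=(3, nlat, nlon))
        fut = hist * rng.uniform(0.7, 1.1, size=(3, nlat, nlon))
        crops = {}
        for shift in (0.0, 40.0):
            lats = np.arange(nlat) + 0.5
            lons = np.arange(nlon) + 0.5 + shift
            ocean = make_grid(lats, lons, ["a", "b", "c"], hist, fut, mask=mask)
            crop = make_grid(lats, lons, ["a", "b", "c"], hist, fut, mask=mask)
            se = site_exposure(
                "s", 4.5, 6.5 + shift, ocean, {"rice": crop}, "x",
                n_ocean_cells=10, land_window=5,
            )
            crops[shift] = se
        assert crops[0.0].e_f == pytest.approx(crops[40.0].e_f, abs=1e-9)
        assert crops[0.0].e_a == pytest.approx(crops[40.0].e_a, abs=1e-9)
        assert crops[0.0].e_af == pytest.approx(crops[40.0].e_af, abs=1e-9)


class TestCellCountSensitivity:
    def _grid(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        nlat = nlon = 12
        hist = np.full((4, nlat, nlon), 100.0)
        change = -0.2 + noise * rng.standard_normal((4, nlat, nlon))
        fut = hist * (1 + change)
        return make_grid(
            np.arange(nlat) + 0.5, np.arange(nlon) + 0.5,
            [f"r{k}" for k in range(4)], hist, fut,
        )

    def test_noise_free_mean_identical_at_every_count(self):
        ds = self._grid()
        out = cell_count_sensitivity(5.5, 5.5, ds, counts=(1, 3, 5, 10, 20))
        np.testing.assert_allclose(out["mean"], -20.0, atol=1e-10)

    def test_default_count_matches_pipeline_value(self):
        ds = self._grid(noise=0.05, seed=3)
        out = cell_count_sensitivity(5.5, 5.5, ds, counts=(20,))
        cells = select_ocean_cells(5.5, 5.5, ds, 20)
        want = ensemble_stats(run_relative_change(ds, cells))
        assert out["mean"].iloc[0] == pytest.approx(want.mean)
        assert out["agreement"].iloc[0] == pytest.approx(want.agreement)

    def test_site_variance_decreases_with_cell_count(self):
        """Averaging more cells damps site-to-site scatter from per-cell
        noise (simulation over seeds)."""
        small, large = [], []
        for seed in range(30):
            ds = self._grid(noise=0.15, seed=seed)
            out = cell_count_sensitivity(
                5.5, 5.5, ds, counts=(1, 50)
            ).set_index("n_cells")
            small.append(out.loc[1, "mean"])
            large.append(out.loc[50, "mean"])
        assert np.var(large) < np.var(small)
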