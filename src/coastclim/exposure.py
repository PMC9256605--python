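"""Site-level sector exposure from gridded projection ensembles.

For each community site, fisheries exposure (E_F) is the ensemble change in
total consumer biomass over the twenty nearest ocean cells (great-circle
distance), and agriculture exposure (E_A) averages per-crop yield changes
over land cells in an 11x11 window centred on the site.  Change per run is

    100 * (future mean - historical mean) / historical mean

with means over the selected cells and window years (historical 1983-2013,
mid-century 2046-2056, inclusive).  Runs are then aggregated to an
ensemble mean, 25th/75th percentiles (linear interpolation) and a
direction-agreement fraction.  The composite exposure is
E_AF = (E_A + E_F) / 2.

Conventions (the data sources leave these open): per-run change is computed
first, then aggregated across runs; distance ties at the n-th nearest cell
break lexicographically by (lat, lon); zero-change runs agree with either
sign; runs with a non-positive historical baseline at a site are dropped
and the agreement denominator reduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0

CROPS = ("rice", "maize", "cassava")


def haversine(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.asarray, (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _cell_table(ds: xr.Dataset, want_land: bool) -> pd.DataFrame:
    mask = ds["mask"].values.astype(bool)
    sel = mask if want_land else ~mask
    ii, jj = np.nonzero(sel)
    return pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            "lat": ds["lat"].values[ii],
            "lon": ds["lon"].values[jj],
        }
    )


def select_ocean_cells(
    site_lat: float, site_lon: float, ds: xr.Dataset, n: int = 20
) -> pd.DataFrame:
    """The n nearest ocean cells to the site, nearest first.

    Ties at the cut break lexicographically by (lat, lon) for determinism.
    """
    if n < 1:
        raise ValueError("need n >= 1 ocean cells")
    cells = _cell_table(ds, want_land=False)
    if len(cells) < n:
        raise ValueError(
            f"grid has only {len(cells)} ocean cells; {n} requested"
        )
    cells["distance_km"] = haversine(
        site_lat, site_lon, cells["lat"].values, cells["lon"].values
    )
    cells = cells.sort_values(
        ["distance_km", "lat", "lon"], kind="mergesort"
    ).reset_index(drop=True)
    return cells.head(n)


def select_land_window(
    site_lat: float, site_lon: float, ds: xr.Dataset, window: int = 11
) -> pd.DataFrame:
    """Land cells within a window x window block centred on the site's cell.

    The site's cell is the one whose centre is nearest in great-circle
    distance (robust at cell boundaries).
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    lats, lons = ds["lat"].values, ds["lon"].values
    if not (lats.min() - 1 <= site_lat <= lats.max() + 1) or not (
        lons.min() - 1 <= site_lon <= lons.max() + 1
    ):
        raise ValueError("site outside grid bounds")
    ci = int(np.argmin(np.abs(lats - site_lat)))
    cj = int(np.argmin(np.abs(lons - site_lon)))
    half = window // 2
    i0, i1 = max(0, ci - half), min(len(lats), ci + half + 1)
    j0, j1 = max(0, cj - half), min(len(lons), cj + half + 1)
    mask = ds["mask"].values.astype(bool)
    ii, jj = np.nonzero(mask[i0:i1, j0:j1])
    if len(ii) == 0:
        raise ValueError("no land cells in the window around the site")
    ii, jj = ii + i0, jj + j0
    return pd.DataFrame(
        {"i": ii, "j": jj, "lat": lats[ii], "lon": lons[jj]}
    )


def annualize(ds: xr.Dataset) -> xr.Dataset:
    """Average monthly fields to annual before windowing (no-op if the time
    axis is already annual)."""
    if "month" in ds.dims:
        return ds.mean("month")
    return ds


def run_relative_change(
    ds: xr.Dataset,
    cells: pd.DataFrame,
    historical_window: tuple[int, int] = (1983, 2013),
    future_window: tuple[int, int] = (2046, 2056),
    baseline_tol: float = 1e-9,
) -> np.ndarray:
    """Percent change per run over the selected cells; NaN flags a run whose
    historical baseline at this site is non-positive (excluded downstream)."""
    ds = annualize(ds)
    years = ds["year"].values
    hist_sel = (years >= historical_window[0]) & (years <= historical_window[1])
    fut_sel = (years >= future_window[0]) & (years <= future_window[1])
    if not hist_sel.any() or not fut_sel.any():
        raise ValueError("historical or future window absent from data")
    vals = ds["value"].values  # (run, year, lat, lon)
    ii = cells["i"].to_numpy()
    jj = cells["j"].to_numpy()
    sub = vals[:, :, ii, jj]  # (run, year, cell)
    hist = sub[:, hist_sel].mean(axis=(1, 2))
    fut = sub[:, fut_sel].mean(axis=(1, 2))
    change = np.full(hist.shape, np.nan)
    ok = hist > baseline_tol
    change[ok] = 100.0 * (fut[ok] - hist[ok]) / hist[ok]
    return change


@dataclass
class EnsembleStats:
    mean: float
    p25: float
    p75: float
    agreement: float
    n_runs: int


def ensemble_stats(changes: np.ndarray) -> EnsembleStats:
    """Aggregate per-run changes: mean, quartiles, direction agreement.

    Agreement is the fraction of available runs whose sign matches the sign
    of the ensemble mean; zero-change runs agree with either direction.
    """
    changes = np.asarray(changes, dtype=float)
    ok = changes[np.isfinite(changes)]
    if ok.size == 0:
        raise ValueError("all ensemble runs missing at this site")
    if ok.size < 2:
        raise ValueError("need at least 2 non-missing runs")
    mean = float(ok.mean())
    p25, p75 = np.percentile(ok, [25, 75])
    if mean == 0:
        agreement = 1.0
    else:
        agree = (np.sign(ok) == np.sign(mean)) | (ok == 0)
        agreement = float(agree.mean())
    return EnsembleStats(mean, float(p25), float(p75), agreement, int(ok.size))


def crop_composite(
    crop_changes: dict[str, float], weights: dict[str, float] | None = None
) -> float:
    """Combine per-crop changes into agriculture exposure.

    Unweighted mean by default; optional production-share weights are
    renormalised over the crops present.
    """
    present = {c: v for c, v in crop_changes.items() if v is not None
               and np.isfinite(v)}
    if not present:
        raise ValueError("no crop changes available")
    if weights is None:
        return float(np.mean(list(present.values())))
    w = np.array([weights.get(c, 0.0) for c in present])
    if w.sum() <= 0:
        raise ValueError("crop weights sum to zero over present crops")
    w = w / w.sum()
    return float(np.dot(w, list(present.values())))


def composite_exposure(e_a: float, e_f: float) -> float:
    """E_AF = (E_A + E_F) / 2."""
    return (e_a + e_f) / 2.0


@dataclass
class SiteExposure:
    site_id: str
    scenario: str
    e_f: float
    e_f_p25: float
    e_f_p75: float
    e_f_agreement: float
    e_f_n_runs: int
    e_a: float
    e_a_p25: float
    e_a_p75: float
    e_a_agreement: float
    e_a_n_runs: int
    e_a_crop: dict[str, float] = field(default_factory=dict)
    e_af: float = np.nan

    def as_row(self) -> dict:
        row = {
            "site_id": self.site_id,
            "scenario": self.scenario,
            "E_F": self.e_f,
            "E_F_p25": self.e_f_p25,
            "E_F_p75": self.e_f_p75,
            "E_F_agreement": self.e_f_agreement,
            "E_F_n_runs": self.e_f_n_runs,
            "E_A": self.e_a,
            "E_A_p25": self.e_a_p25,
            "E_A_p75": self.e_a_p75,
            "E_A_agreement": self.e_a_agreement,
            "E_A_n_runs": self.e_a_n_runs,
            "E_AF": self.e_af,
        }
        row.update({f"E_A_{c}": v for c, v in self.e_a_crop.items()})
        return row


def _per_run_crop_changes(
    grids: dict[str, xr.Dataset],
    cells: pd.DataFrame,
    historical_window,
    future_window,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-run agriculture composite, aligned on run name across crops.

    Cassava exists only for its single model family; for runs without
    cassava the composite averages the crops that run simulated.  Returns
    (per-run table indexed by run, per-crop ensemble-mean change).
    """
    per_crop: dict[str, pd.Series] = {}
    for crop, ds in grids.items():
        ch = run_relative_change(ds, cells, historical_window, future_window)
        per_crop[crop] = pd.Series(ch, index=ds["run"].values, name=crop)
    table = pd.DataFrame(per_crop)
    crop_means = {
        c: float(np.nanmean(s.values)) if np.isfinite(s.values).any() else np.nan
        for c, s in per_crop.items()
    }
    return table, crop_means


def site_exposure(
    site_id: str,
    site_lat: float,
    site_lon: float,
    ocean_ds: xr.Dataset,
    crop_grids: dict[str, xr.Dataset],
    scenario: str,
    n_ocean_cells: int = 20,
    land_window: int = 11,
    historical_window: tuple[int, int] = (1983, 2013),
    future_window: tuple[int, int] = (2046, 2056),
    crop_weights: dict[str, float] | None = None,
) -> SiteExposure:
    """Full exposure extraction for one site under one scenario."""
    ocean_cells = select_ocean_cells(site_lat, site_lon, ocean_ds, n_ocean_cells)
    f_changes = run_relative_change(
        ocean_ds, ocean_cells, historical_window, future_window
    )
    f_stats = ensemble_stats(f_changes)

    any_crop = next(iter(crop_grids.values()))
    land_cells = select_land_window(site_lat, site_lon, any_crop, land_window)
    run_table, crop_means = _per_run_crop_changes(
        crop_grids, land_cells, historical_window, future_window
    )
    per_run_ea = np.array([
        crop_composite(
            {c: row[c] for c in run_table.columns if np.isfinite(row[c])},
            weights=crop_weights,
        )
        if np.isfinite(row.values).any()
        else np.nan
        for _, row in run_table.iterrows()
    ])
    a_stats = ensemble_stats(per_run_ea)
    e_a = crop_composite(crop_means, weights=crop_weights)
    return SiteExposure(
        site_id=site_id,
        scenario=scenario,
        e_f=f_stats.mean, e_f_p25=f_stats.p25, e_f_p75=f_stats.p75,
        e_f_agreement=f_stats.agreement, e_f_n_runs=f_stats.n_runs,
        e_a=e_a, e_a_p25=a_stats.p25, e_a_p75=a_stats.p75,
        e_a_agreement=a_stats.agreement, e_a_n_runs=a_stats.n_runs,
        e_a_crop=crop_means,
        e_af=composite_exposure(e_a, f_stats.mean),
    )


def extract_exposures(
    sites: pd.DataFrame,
    ocean: dict[str, xr.Dataset],
    crops: dict[str, dict[str, xr.Dataset]],
    scenarios: tuple[str, ...],
    **kwargs,
) -> pd.DataFrame:
    """Exposure table for every site x scenario.

    ``sites`` needs columns site-or-community id, lat, lon (first column is
    used as the id when no ``site_id`` column exists).
    """
    id_col = "site_id" if "site_id" in sites.columns else sites.columns[0]
    rows = []
    for scenario in scenarios:
        crop_grids = {c: crops[c][scenario] for c in crops}
        for _, s in sites.iterrows():
            se = site_exposure(
                str(s[id_col]), float(s["lat"]), float(s["lon"]),
                ocean[scenario], crop_grids, scenario, **kwargs,
            )
            row = se.as_row()
            row[id_col] = str(s[id_col])
            if "country" in sites.columns:
                row["country"] = s["country"]
            rows.append(row)
    return pd.DataFrame(rows)


def cell_count_sensitivity(
    site_lat: float,
    site_lon: float,
    ocean_ds: xr.Dataset,
    counts: tuple[int, ...] = (1, 3, 5, 10, 20, 50, 100),
    historical_window: tuple[int, int] = (1983, 2013),
    future_window: tuple[int, int] = (2046, 2056),
) -> pd.DataFrame:
    """Ensemble statistics as a function of the number of ocean cells used.

    Mirrors the choice-of-twenty analysis: agreement and mean per cell
    count (single-run changes cannot support quartiles, so counts of 1 are
    allowed but still aggregate across runs, not cells).
    """
    rows = []
    for n in counts:
        cells = select_ocean_cells(site_lat, site_lon, ocean_ds, n)
        changes = run_relative_change(
            ocean_ds, cells, historical_window, future_window
        )
        st = ensemble_stats(changes)
        rows.append(
            {
                "n_cells": n,
                "mean": st.mean,
                "p25": st.p25,
                "p75": st.p75,
                "agreement": st.agreement,
                "n_runs": st.n_runs,
            }
        )
    return pd.DataFrame(rows)
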