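import numpy as np
import pandas as pd
import pytest
import xarray as xr

from coastclim.config import GridSpec, SyntheticConfig


@pytest.fixture
def tiny_config() -> SyntheticConfig:
    """Small synthetic world: 2 countries, 12 communities, 10x10 deg box."""
    return SyntheticConfig(
        seed=7,
        n_countries=2,
        communities_per_country=(6, 6),
        households_range=(10, 25),
        sector_engagement_probs=((0.25, 0.25, 0.35, 0.15),) * 2,
        grid=GridSpec(lon_min=110, lon_max=120, lat_min=-5, lat_max=5),
    )


def make_grid(
    lat, lon, runs, hist, fut, mask=None,
    hist_years=(1983, 2013), fut_years=(2046, 2056),
) -> xr.Dataset:
    """Hand-built ensemble dataset: ``hist``/``fut`` are (run, lat, lon)
    arrays (or scalars), constant over the years of each window."""
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    years = np.concatenate(
        [np.arange(hist_years[0], hist_years[1] + 1),
         np.arange(fut_years[0], fut_years[1] + 1)]
    )
    n_hist = hist_years[1] - hist_years[0] + 1
    shape = (len(runs), len(lat), len(lon))
    hist = np.broadcast_to(np.asarray(hist, float), shape)
    fut = np.broadcast_to(np.asarray(fut, float), shape)
    values = np.empty((len(runs), len(years), len(lat), len(lon)))
    values[:, :n_hist] = hist[:, None]
    values[:, n_hist:] = fut[:, None]
    if mask is None:
        mask = np.zeros((len(lat), len(lon)), dtype=np.int8)
    return xr.Dataset(
        {
            "value": (("run", "year", "lat", "lon"), values),
            "mask": (("lat", "lon"), np.asarray(mask, dtype=np.int8)),
        },
        coords={"run": list(runs), "year": years, "lat": lat, "lon": lon},
    )
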