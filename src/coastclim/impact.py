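"""Potential impact: combining sensitivity and exposure.

Relative potential impact is the Euclidean distance from the origin of a
community's (sensitivity, exposure) pair after both are placed on a common
[0, 1] scale across the community set: sensitivity is min-max scaled, and
exposure is first converted to a loss (positive = productivity loss, gains
floored at zero) then min-max scaled.  The distance is therefore monotone
in harm on both axes and bounded by sqrt(2).  A raw-units variant (no loss
flooring, joint min-max on the signed exposure) is available since the
joint scaling of a bounded index with a percentage is a genuine choice.

A community suffers a *double burden* when both sector exposures are
negative (simultaneous projected losses in fisheries and agriculture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr


def minmax_scale(values: np.ndarray, bounds: tuple[float, float] | None = None
                 ) -> np.ndarray:
    """Min-max scale to [0, 1]; explicit bounds allow degenerate sets."""
    v = np.asarray(values, dtype=float)
    if bounds is not None:
        lo, hi = bounds
    else:
        if v.size < 2:
            raise ValueError(
                "cannot min-max scale a single value without explicit bounds"
            )
        lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def exposure_loss(exposure_pct: np.ndarray) -> np.ndarray:
    """Signed percent change -> non-negative loss (gains floor at zero)."""
    e = np.asarray(exposure_pct, dtype=float)
    return np.where(e < 0, -e, 0.0)


def potential_impact(
    sensitivity: np.ndarray,
    exposure_pct: np.ndarray,
    sensitivity_bounds: tuple[float, float] | None = None,
    exposure_bounds: tuple[float, float] | None = None,
    scaling: str = "loss",
) -> pd.DataFrame:
    """Per-community scaled components and Euclidean potential impact.

    ``scaling='loss'`` (default) floors exposure gains at zero loss before
    scaling; ``'signed'`` min-max scales the signed change and measures
    distance from the most favourable corner (larger loss = larger value).
    """
    s = np.asarray(sensitivity, dtype=float)
    e = np.asarray(exposure_pct, dtype=float)
    if s.shape != e.shape:
        raise ValueError("sensitivity and exposure must align")
    if s.size < 2 and (sensitivity_bounds is None or exposure_bounds is None):
        raise ValueError(
            "a single community cannot be scaled without explicit bounds"
        )
    s_scaled = minmax_scale(s, sensitivity_bounds)
    if scaling == "loss":
        e_scaled = minmax_scale(exposure_loss(e), exposure_bounds)
    elif scaling == "signed":
        # high value = worst (most negative) change
        e_scaled = 1.0 - minmax_scale(e, exposure_bounds)
    else:
        raise ValueError(f"unknown scaling: {scaling!r}")
    impact = np.sqrt(s_scaled**2 + e_scaled**2)
    return pd.DataFrame(
        {
            "scaled_sensitivity": s_scaled,
            "scaled_exposure_loss": e_scaled,
            "potential_impact": impact,
        }
    )


def double_burden(e_a, e_f) -> np.ndarray:
    """True where both sector exposures are losses (strictly negative)."""
    return (np.asarray(e_a, float) < 0) & (np.asarray(e_f, float) < 0)


def cohort_rate(flags) -> float:
    """Fraction of communities flagged."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("empty cohort")
    return float(flags.mean())


@dataclass
class ImpactTable:
    records: pd.DataFrame


def build_impact_table(
    sensitivity_df: pd.DataFrame,
    exposure_df: pd.DataFrame,
    scaling: str = "loss",
) -> pd.DataFrame:
    """Join community sensitivity (S_AF) with exposure and compute impact.

    Scaling is done within scenario across the full community set, so
    scores are comparable between communities under one scenario.
    """
    expo = exposure_df.copy()
    if "community_id" not in expo.columns:
        expo["community_id"] = expo["site_id"]
    keep = ["community_id", "S_A", "S_F", "S_AF"] + [
        c for c in ("msl_raw", "msl_scaled") if c in sensitivity_df.columns
    ]
    merged = expo.merge(sensitivity_df[keep], on="community_id", how="inner")
    if merged.empty:
        raise ValueError("no overlap between sensitivity and exposure tables")
    out = []
    for scenario, grp in merged.groupby("scenario", sort=True):
        grp = grp.reset_index(drop=True)
        pi = potential_impact(
            grp["S_AF"].to_numpy(), grp["E_AF"].to_numpy(), scaling=scaling
        )
        grp = pd.concat([grp, pi], axis=1)
        grp["double_burden"] = double_burden(
            grp["E_A"].to_numpy(), grp["E_F"].to_numpy()
        )
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def random_coastal_sample(
    population: xr.Dataset,
    threshold: float = 25.0,
    fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Random coastal sites for the site-representativeness check.

    Eligible cells are coastal (land adjacent to ocean) with population
    density strictly above ``threshold`` people/km2; a without-replacement
    sample of floor(fraction * n_eligible) cells is drawn reproducibly.
    """
    coastal = population["coastal"].values.astype(bool)
    dens = population["density"].values
    eligible = coastal & (dens > threshold)
    ii, jj = np.nonzero(eligible)
    n_eligible = len(ii)
    if n_eligible == 0:
        raise ValueError("no eligible coastal cells above the density threshold")
    n_sample = int(np.floor(fraction * n_eligible))
    if n_sample < 1:
        raise ValueError("sample fraction selects zero cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_eligible, size=n_sample, replace=False)
    lats = population["lat"].values[ii[pick]]
    lons = population["lon"].values[jj[pick]]
    return pd.DataFrame(
        {
            "site_id": [f"rand_{k}" for k in range(n_sample)],
            "lat": lats,
            "lon": lons,
        }
    )
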