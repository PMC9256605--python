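"""Community livelihood sensitivity and material-style-of-life wealth.

Sensitivity to a sector is a three-factor index per community:

    S = X/(X+NX) * N/(X+NX) * ((r_x/2) + 1) / (r_x + r_nx + 1)

where X counts households relying on the focal sector, NX those relying on
any occupation outside it, N the community's households, and r_x / r_nx how
many households rank the focal sector above / below its counterpart.  The
index multiplies engagement (how many households are in the sector),
linkage (how exclusively they are in it) and directionality (whether the
sector tends to be the most important occupation).  Each factor lies in
[0, 1] whenever every household lists at least one occupation, so S does
too, and S = 0 exactly when no household engages in the sector.

The material style of life (MSL) score is the first principal axis of the
16 binary material-item indicators, oriented so more items means a higher
score; community means are min-max rescaled to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

FISHERIES = "fisheries"
AGRICULTURE = "agriculture"
OFF = "off"
JOINT = "joint"

#: Occupation category -> sector.
SECTOR_MAP: dict[str, str] = {
    "fishing": FISHERIES,
    "mariculture": FISHERIES,
    "gleaning": FISHERIES,
    "fish_trading": FISHERIES,
    "farming": AGRICULTURE,
    "cash_crop": AGRICULTURE,
    "salaried": OFF,
    "informal": OFF,
    "tourism": OFF,
    "other": OFF,
}


@dataclass(frozen=True)
class HouseholdClass:
    """Sector engagement flags and the best (lowest) rank per sector."""

    fisheries: bool
    agriculture: bool
    off: bool
    best_rank: dict  # sector -> best rank (absent if not engaged)


def classify_household(
    occupations: list[tuple[str, int]],
    sector_map: dict[str, str] = SECTOR_MAP,
) -> HouseholdClass:
    """Classify one household's ranked occupation list.

    ``occupations`` is a list of (category, rank) with rank 1 the most
    important; ranks must be distinct.
    """
    if not occupations:
        raise ValueError("household lists no occupations")
    ranks = [r for _, r in occupations]
    if len(set(ranks)) != len(ranks):
        raise ValueError("occupation ranks must be distinct within a household")
    best: dict[str, int] = {}
    for occ, rank in occupations:
        if occ not in sector_map:
            raise KeyError(f"unknown occupation category: {occ!r}")
        sector = sector_map[occ]
        if sector not in best or rank < best[sector]:
            best[sector] = rank
    return HouseholdClass(
        fisheries=FISHERIES in best,
        agriculture=AGRICULTURE in best,
        off=OFF in best,
        best_rank=best,
    )


@dataclass
class SectorCounts:
    """Ingredients of the sensitivity index for one community and focal
    sector (or the joint fisheries-and-agriculture focal)."""

    focal: str
    X: int
    NX: int
    N: int
    r_x: int
    r_nx: int


def _focal_counterpart(focal: str, joint_counterpart: str):
    if focal == AGRICULTURE:
        return {AGRICULTURE}, {FISHERIES, OFF}
    if focal == FISHERIES:
        return {FISHERIES}, {AGRICULTURE, OFF}
    if focal == JOINT:
        if joint_counterpart == "off":
            return {FISHERIES, AGRICULTURE}, {OFF}
        return {FISHERIES, AGRICULTURE}, {OFF}  # complement of joint == off
    raise ValueError(f"unknown focal sector: {focal!r}")


def sector_counts(
    households: list[HouseholdClass],
    focal: str,
    rank_rule: str = "household",
    joint_counterpart: str = "off",
) -> SectorCounts:
    """Count engagement and ranking direction for a community.

    ``rank_rule='household'`` (default) gives one increment per dual-engaged
    household by comparing best ranks; ``'pairs'`` counts every
    focal/counterpart occupation pair.
    """
    if not households:
        raise ValueError("community has no households")
    focal_set, counter_set = _focal_counterpart(focal, joint_counterpart)

    def engaged(h: HouseholdClass, sectors: set[str]) -> bool:
        return any(s in h.best_rank for s in sectors)

    X = sum(engaged(h, focal_set) for h in households)
    NX = sum(engaged(h, counter_set) for h in households)
    r_x = r_nx = 0
    for h in households:
        if not (engaged(h, focal_set) and engaged(h, counter_set)):
            continue
        if rank_rule == "household":
            bf = min(h.best_rank[s] for s in focal_set if s in h.best_rank)
            bc = min(h.best_rank[s] for s in counter_set if s in h.best_rank)
            if bf < bc:
                r_x += 1
            else:
                r_nx += 1
        elif rank_rule == "pairs":
            # best_rank only keeps one rank per sector, so pair counting
            # needs the full lists; HouseholdClass carries sector bests only.
            raise NotImplementedError(
                "pair-level counting requires count_community(..., rank_rule='pairs')"
            )
        else:
            raise ValueError(f"unknown rank rule: {rank_rule!r}")
    return SectorCounts(focal=focal, X=X, NX=NX, N=len(households),
                        r_x=r_x, r_nx=r_nx)


def sector_counts_pairs(
    households: list[list[tuple[str, int]]],
    focal: str,
    sector_map: dict[str, str] = SECTOR_MAP,
    joint_counterpart: str = "off",
) -> SectorCounts:
    """Pair-level alternative to the household-level ranking rule."""
    classes = [classify_household(h, sector_map) for h in households]
    base = sector_counts(classes, focal, joint_counterpart=joint_counterpart)
    focal_set, counter_set = _focal_counterpart(focal, joint_counterpart)
    r_x = r_nx = 0
    for occs in households:
        focal_occs = [r for o, r in occs if sector_map[o] in focal_set]
        counter_occs = [r for o, r in occs if sector_map[o] in counter_set]
        for rf in focal_occs:
            for rc in counter_occs:
                if rf < rc:
                    r_x += 1
                else:
                    r_nx += 1
    base.r_x, base.r_nx = r_x, r_nx
    return base


def sensitivity_index(counts: SectorCounts) -> float:
    """Evaluate the three-factor sensitivity index from its counts."""
    if counts.N < 1:
        raise ValueError("community has no households")
    denom = counts.X + counts.NX
    if denom == 0:
        raise ValueError("no occupations in community (X + NX = 0)")
    engagement = counts.X / denom
    linkage = counts.N / denom
    direction = ((counts.r_x / 2) + 1) / (counts.r_x + counts.r_nx + 1)
    return engagement * linkage * direction


def sensitivity_factors(counts: SectorCounts) -> dict[str, float]:
    denom = counts.X + counts.NX
    return {
        "engagement": counts.X / denom,
        "linkage": counts.N / denom,
        "direction": ((counts.r_x / 2) + 1) / (counts.r_x + counts.r_nx + 1),
    }


def _households_from_long(df: pd.DataFrame) -> dict[str, list[tuple[str, int]]]:
    out: dict[str, list[tuple[str, int]]] = {}
    for hid, grp in df.groupby("household_id", sort=True):
        occs = list(zip(grp["occupation_category"], grp["rank"].astype(int)))
        if not occs:
            logger.warning("household %s lists no occupations; dropped", hid)
            continue
        out[str(hid)] = occs
    return out


def community_sensitivity(
    long_df: pd.DataFrame,
    sector_map: dict[str, str] = SECTOR_MAP,
    rank_rule: str = "household",
) -> pd.DataFrame:
    """Per-community S_A, S_F and S_AF from the long survey table.

    Expects columns community_id, country, household_id,
    occupation_category, rank.  Households with zero occupations are
    dropped with a warning.
    """
    recs = []
    for (community, country), grp in long_df.groupby(
        ["community_id", "country"], sort=True
    ):
        houses = _households_from_long(grp)
        classes = [classify_household(o, sector_map) for o in houses.values()]
        row = {"community_id": community, "country": country,
               "N": len(classes)}
        for focal, label in ((AGRICULTURE, "S_A"), (FISHERIES, "S_F"),
                             (JOINT, "S_AF")):
            if rank_rule == "pairs":
                counts = sector_counts_pairs(
                    list(houses.values()), focal, sector_map
                )
            else:
                counts = sector_counts(classes, focal, rank_rule=rank_rule)
            row[label] = sensitivity_index(counts)
            fac = sensitivity_factors(counts)
            row.update({f"{label}_{k}": v for k, v in fac.items()})
        recs.append(row)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# material style of life
# ---------------------------------------------------------------------------

@dataclass
class MSLResult:
    household_scores: pd.DataFrame  # household_id, community_id, country, score
    loadings: pd.DataFrame          # item, pc1 (and pc2 when requested)
    variance_explained: float
    community_scores: pd.DataFrame  # community_id, country, msl_raw, msl_scaled


ITEM_COLUMNS = [f"item_{j:02d}" for j in range(16)]


def msl_scores(items_df: pd.DataFrame, n_components: int = 1) -> MSLResult:
    """First-principal-axis wealth score from the 16 binary items.

    PCA is run on the centred (not standardised) item matrix, the usual
    covariance form for asset indices.  The axis is oriented so households
    owning more items score higher.  Community mean scores are min-max
    rescaled to [0, 1] across communities.
    """
    cols = [c for c in ITEM_COLUMNS if c in items_df.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 item columns")
    X = items_df[cols].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 households for a principal axis")
    if np.count_nonzero(X.var(axis=0) > 0) < 2:
        raise ValueError("item matrix has fewer than 2 varying items")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    # orient: richer (more items) = higher score
    for k in range(n_components):
        corr = np.corrcoef(scores[:, k], X.sum(axis=1))[0, 1]
        if np.isfinite(corr) and corr < 0:
            scores[:, k] *= -1
            pca.components_[k] *= -1
    hh = items_df[["household_id", "community_id", "country"]].copy()
    hh["score"] = scores[:, 0]
    if n_components > 1:
        hh["score2"] = scores[:, 1]
    load = pd.DataFrame({"item": cols, "pc1": pca.components_[0]})
    if n_components > 1:
        load["pc2"] = pca.components_[1]
    comm = (
        hh.groupby(["community_id", "country"], sort=True)["score"]
        .mean()
        .reset_index()
        .rename(columns={"score": "msl_raw"})
    )
    lo, hi = comm["msl_raw"].min(), comm["msl_raw"].max()
    if hi > lo:
        comm["msl_scaled"] = (comm["msl_raw"] - lo) / (hi - lo)
    else:
        comm["msl_scaled"] = 0.0
    return MSLResult(
        household_scores=hh,
        loadings=load,
        variance_explained=float(pca.explained_variance_ratio_[0]),
        community_scores=comm,
    )


def temporal_trajectory(
    waves: dict[object, tuple[pd.DataFrame, pd.DataFrame]],
) -> pd.DataFrame:
    """Track one community through repeated survey waves.

    ``waves`` maps a wave label (e.g. survey year) to its (long, items)
    tables.  One PCA is fitted on households pooled across all waves; each
    wave's centroid is projected into that common two-axis space, and the
    joint fisheries-agriculture sensitivity is recomputed per wave.
    Returns one row per wave: pc1, pc2, S_AF, n_households.
    """
    if len(waves) < 2:
        raise ValueError("need at least two survey waves")
    pooled = []
    for wave, (_, items) in sorted(waves.items(), key=lambda kv: str(kv[0])):
        if items.shape[0] < 2:
            raise ValueError(f"wave {wave!r} has fewer than 2 households")
        tagged = items.copy()
        tagged["_wave"] = wave
        pooled.append(tagged)
    allitems = pd.concat(pooled, ignore_index=True)
    res = msl_scores(allitems, n_components=2)
    scored = res.household_scores.copy()
    scored["_wave"] = allitems["_wave"].values
    recs = []
    for wave, (long_df, _) in sorted(waves.items(), key=lambda kv: str(kv[0])):
        sens = community_sensitivity(long_df)
        sub = scored[scored["_wave"] == wave]
        recs.append(
            {
                "wave": wave,
                "pc1": float(sub["score"].mean()),
                "pc2": float(sub["score2"].mean()),
                "S_AF": float(sens["S_AF"].mean()),
                "n_households": int(sub.shape[0]),
            }
        )
    return pd.DataFrame(recs)
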