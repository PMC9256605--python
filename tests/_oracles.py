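"""Independent brute-force reference implementations used by the tests.

These deliberately re-derive quantities from first principles (direct
enumeration, dense sorts, closed forms) without touching the package's own
code paths, so they can serve as oracles.
"""

from __future__ import annotations

import numpy as np

FISH = {"fishing", "mariculture", "gleaning", "fish_trading"}
AG = {"farming", "cash_crop"}
OFF = {"salaried", "informal", "tourism", "other"}
ALL_OCCS = sorted(FISH | AG | OFF)


def oracle_sensitivity(households: list[list[tuple[str, int]]], focal: str) -> float:
    """Direct household enumeration of the three-factor sensitivity index.

    ``focal`` is 'A', 'F' or 'AF'.  The counterpart of the joint focal is
    the off-sector.
    """
    if focal == "A":
        focal_occ, counter_occ = AG, FISH | OFF
    elif focal == "F":
        focal_occ, counter_occ = FISH, AG | OFF
    elif focal == "AF":
        focal_occ, counter_occ = AG | FISH, OFF
    else:
        raise ValueError(focal)
    N = len(households)
    X = NX = r_x = r_nx = 0
    for house in households:
        in_focal = [r for o, r in house if o in focal_occ]
        in_counter = [r for o, r in house if o in counter_occ]
        if in_focal:
            X += 1
        if in_counter:
            NX += 1
        if in_focal and in_counter:
            if min(in_focal) < min(in_counter):
                r_x += 1
            else:
                r_nx += 1
    if X + NX == 0:
        raise ValueError("no occupations")
    return (X / (X + NX)) * (N / (X + NX)) * (((r_x / 2) + 1) / (r_x + r_nx + 1))


def random_community(rng: np.random.Generator, n_households: int
                     ) -> list[list[tuple[str, int]]]:
    """Random community: each household holds 1-4 distinct occupations with
    a random importance permutation."""
    community = []
    for _ in range(n_households):
        k = int(rng.integers(1, 5))
        occs = rng.choice(ALL_OCCS, size=k, replace=False)
        ranks = rng.permutation(k) + 1
        community.append([(str(o), int(r)) for o, r in zip(occs, ranks)])
    return community


def oracle_nearest_cells(site_lat, site_lon, cell_lats, cell_lons, n):
    """Exhaustive haversine sort over all cells (lex tie-break)."""
    R = 6371.0
    p1 = np.radians(site_lat)
    p2 = np.radians(np.asarray(cell_lats))
    dl = np.radians(np.asarray(cell_lons) - site_lon)
    a = (np.sin((p2 - p1) / 2) ** 2
         + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2)
    d = 2 * R * np.arcsin(np.sqrt(a))
    order = np.lexsort((cell_lons, cell_lats, d))
    return order[:n]


def oracle_cohens_d(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    return (np.mean(a) - np.mean(b)) / np.sqrt(sp2)
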