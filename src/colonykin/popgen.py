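"""Regional diversity, pairwise differentiation, and isolation by distance.

Expected heterozygosity is averaged over variable sites per region on a
reduced sample (one least-missing worker per colony plus all transect
singletons) so family structure does not depress the estimate.  Pairwise
colony differentiation uses the Weir–Cockerham variance-components F_ST
(ratio-of-sums aggregation).  Isolation by distance regresses Rousset's
transformed genetic distance F_ST/(1-F_ST) on great-circle distance in
meters, with significance from a Mantel permutation of colony labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, cos, radians, sin, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeTable

EARTH_RADIUS_M = 6_371_000.0


# ---------------------------------------------------------------------------
# diversity


def least_missing_representatives(table: GenotypeTable, metadata: pd.DataFrame) -> list:
    """One sample per colony (the one with the least missing data, ties by
    sample id) plus every transect sample present in the table."""
    miss = dict(zip(table.samples, table.sample_missing_fraction()))
    present = metadata[metadata["sample"].isin(table.samples)]
    chosen = []
    for colony, grp in present[present["origin"] == "colony"].groupby("colony"):
        best = sorted(grp["sample"], key=lambda s: (miss[s], s))[0]
        chosen.append(best)
    chosen += sorted(present.loc[present["origin"] == "transect", "sample"])
    return chosen


def expected_heterozygosity(table: GenotypeTable, sample_names: list) -> float:
    """Mean per-variable-site nucleotide diversity in the given subset.

    Per site, ``pi = 2 p (1-p) n/(n-1)`` with n the called allele count;
    the value is the mean over sites variable within the subset, or 0.0
    when no site is variable.
    """
    sub = table.select_samples(sample_names)
    p = sub.alt_freqs()
    n = sub.allele_counts().astype(float)
    variable = ~np.isnan(p) & (p > 0) & (p < 1) & (n >= 2)
    if not variable.any():
        return 0.0
    p, n = p[variable], n[variable]
    pi = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return float(pi.mean())


def regional_heterozygosity(
    table: GenotypeTable, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-region expected heterozygosity on the reduced sample."""
    reps = least_missing_representatives(table, metadata)
    meta = metadata.set_index("sample")
    rows = []
    for region, grp in metadata[metadata["sample"].isin(reps)].groupby("region"):
        names = list(grp["sample"])
        rows.append(
            {
                "region": region,
                "n_samples": len(names),
                "expected_heterozygosity": expected_heterozygosity(table, names),
                "low_confidence": len(names) < 2,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def weir_cockerham_fst(
    table: GenotypeTable, group_a: list, group_b: list
) -> float:
    """Two-population Weir–Cockerham F_ST, ratio-of-sums over loci.

    Per locus the among- (a), between-individual (b) and within-individual
    (c) variance components are computed from sample sizes, allele
    frequencies, and observed heterozygote proportions; the estimate is
    ``sum(a) / sum(a + b + c)``.  Loci with an undefined denominator are
    skipped.  The estimate is left unclipped (slightly negative values are
    legitimate for undifferentiated groups).
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    ga = table.select_samples(group_a).genotypes
    gb = table.select_samples(group_b).genotypes
    num, den = _wc_components(ga, gb)
    if den == 0:
        return float("nan")
    return float(num / den)


def _wc_components(ga: np.ndarray, gb: np.ndarray) -> tuple[float, float]:
    """Return (sum of a, sum of a+b+c) over usable loci for two groups."""
    r = 2.0
    total_a = total_abc = 0.0
    n_a = (~np.isnan(ga)).sum(axis=0).astype(float)
    n_b = (~np.isnan(gb)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p_a = np.nanmean(ga, axis=0) / 2.0
        p_b = np.nanmean(gb, axis=0) / 2.0
        h_a = np.nanmean(ga == 1, axis=0)
        h_b = np.nanmean(gb == 1, axis=0)
    # require data in both groups and an overall polymorphic locus
    usable = (n_a >= 2) & (n_b >= 2)
    for j in np.where(usable)[0]:
        ni = np.array([n_a[j], n_b[j]])
        pi = np.array([p_a[j], p_b[j]])
        hi = np.array([h_a[j], h_b[j]])
        nbar = ni.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ni**2).sum() / (r * nbar)) / (r - 1.0)
        if nc == 0:
            continue
        pbar = (ni * pi).sum() / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        s2 = (ni * (pi - pbar) ** 2).sum() / ((r - 1.0) * nbar)
        hbar = (ni * hi).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        total_a += a
        total_abc += a + b + c
    return total_a, total_abc


def pairwise_colony_fst(
    table: GenotypeTable, metadata: pd.DataFrame, min_workers: int = 6
) -> pd.DataFrame:
    """F_ST between every pair of colonies with at least ``min_workers``
    genotyped workers; long format, one row per unordered pair."""
    meta = metadata[(metadata["origin"] == "colony") & metadata["sample"].isin(table.samples)]
    groups = {
        colony: list(grp["sample"])
        for colony, grp in meta.groupby("colony")
        if len(grp) >= min_workers
    }
    colonies = sorted(groups)
    rows = []
    for i, ca in enumerate(colonies):
        for cb in colonies[i + 1 :]:
            rows.append(
                {
                    "colony_a": ca,
                    "colony_b": cb,
                    "fst": weir_cockerham_fst(table, groups[ca], groups[cb]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geography


def great_circle_distance(coord_a: tuple, coord_b: tuple) -> float:
    """Haversine distance in meters on a sphere of radius 6,371,000 m."""
    (lat1, lon1), (lat2, lon2) = coord_a, coord_b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
            raise ValueError(f"invalid coordinate ({lat}, {lon})")
    phi1, phi2 = radians(lat1), radians(lat2)
    dphi = radians(lat2 - lat1)
    dlmb = radians(lon2 - lon1)
    h = sin(dphi / 2.0) ** 2 + cos(phi1) * cos(phi2) * sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * asin(min(1.0, sqrt(h)))


def rousset_distance(fst: float) -> float:
    """F_ST / (1 - F_ST); linear in distance under 2-D isolation by distance."""
    if fst >= 1.0:
        raise ValueError("Rousset transform undefined at F_ST = 1")
    return fst / (1.0 - fst)


# ---------------------------------------------------------------------------
# isolation by distance


@dataclass
class IBDResult:
    """Regression of Rousset's distance on geographic distance."""

    pairs: pd.DataFrame  # colony_a, colony_b, fst, rousset, meters
    slope: float
    intercept: float
    r2: float
    mantel_p: float
    n_permutations: int


def ibd_regression(
    fst_pairs: pd.DataFrame,
    colony_coords: dict,
    n_permutations: int = 9999,
    seed: int = 0,
) -> IBDResult:
    """Isolation-by-distance regression with a Mantel permutation test.

    ``fst_pairs`` has columns colony_a, colony_b, fst; ``colony_coords``
    maps colony -> (lat, lon).  OLS of F_ST/(1-F_ST) on meters; the
    one-sided p-value (positive association) permutes colony labels of the
    genetic matrix jointly over rows and columns, and is lower-bounded by
    1/(n_permutations + 1).  Pairs with F_ST = 1 are dropped with a warning
    column in the output.
    """
    pairs = fst_pairs.copy()
    ok = pairs["fst"] < 1.0
    pairs = pairs[ok].reset_index(drop=True)
    if len(pairs) < 3:
        raise ValueError("isolation by distance needs >= 3 colony pairs")
    colonies = sorted(set(pairs["colony_a"]) | set(pairs["colony_b"]))
    idx = {c: i for i, c in enumerate(colonies)}
    k = len(colonies)
    gen = np.full((k, k), np.nan)
    geo = np.full((k, k), np.nan)
    pairs["rousset"] = [rousset_distance(f) for f in pairs["fst"]]
    pairs["meters"] = [
        great_circle_distance(colony_coords[a], colony_coords[b])
        for a, b in zip(pairs["colony_a"], pairs["colony_b"])
    ]
    for _, row in pairs.iterrows():
        i, j = idx[row["colony_a"]], idx[row["colony_b"]]
        gen[i, j] = gen[j, i] = row["rousset"]
        geo[i, j] = geo[j, i] = row["meters"]

    iu = np.triu_indices(k, 1)
    mask = ~np.isnan(gen[iu]) & ~np.isnan(geo[iu])
    x = geo[iu][mask]
    y = gen[iu][mask]
    res = stats.linregress(x, y)
    obs_r = res.rvalue

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        yp = gen[np.ix_(perm, perm)][iu][mask]
        ok_p = ~np.isnan(yp)
        if ok_p.sum() < 3 or np.std(yp[ok_p]) == 0:
            continue
        r = np.corrcoef(x[ok_p], yp[ok_p])[0, 1]
        if r >= obs_r:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return IBDResult(
        pairs=pairs,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        mantel_p=float(p),
        n_permutations=n_permutations,
    )
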