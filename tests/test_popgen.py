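"""Diversity, Weir-Cockerham F_ST, geography, isolation by distance."""

import numpy as np
import pandas as pd
import pytest

from colonykin.popgen import (
    EARTH_RADIUS_M,
    expected_heterozygosity,
    great_circle_distance,
    ibd_regression,
    least_missing_representatives,
    pairwise_colony_fst,
    regional_heterozygosity,
    rousset_distance,
    weir_cockerham_fst,
)
from colonykin.simulate import draw_region_frequencies

from ._util import hwe_dosages, make_table


# ---------------------------------------------------------------------------
# expected heterozygosity


def test_fixed_region_diversity_zero():
    g = np.full((5, 10), 2.0)
    t = make_table(g)
    assert expected_heterozygosity(t, t.samples) == 0.0


def test_single_site_closed_form():
    # p = 0.5, n = 4 alleles -> pi = 2*0.25*(4/3) = 2/3
    g = np.array([[0.0], [2.0]])
    t = make_table(g)
    assert expected_heterozygosity(t, t.samples) == pytest.approx(2.0 / 3.0)


def test_balding_nichols_regions_homogeneous_diversity():
    """Symmetric divergence from one ancestral pool leaves regional
    diversity homogeneous (no geographic trend by construction)."""
    rng = np.random.default_rng(127)
    anc = rng.uniform(0.1, 0.9, 2000)
    freqs = draw_region_frequencies(anc, 0.2, 3, rng)
    vals = []
    for r in range(3):
        g = hwe_dosages(20, freqs[r], rng)
        t = make_table(g)
        vals.append(expected_heterozygosity(t, t.samples))
    assert max(vals) - min(vals) < 0.03


def test_representative_selection_prefers_least_missing():
    g = np.ones((4, 10))
    g[0, :4] = np.nan
    t = make_table(g)
    meta = pd.DataFrame(
        {
            "sample": t.samples,
            "colony": ["C1", "C1", "C2", ""],
            "region": "r1",
            "lat": 50.0,
            "lon": -115.0,
            "origin": ["colony", "colony", "colony", "transect"],
        }
    )
    reps = least_missing_representatives(t, meta)
    assert reps == ["s2", "s3", "s4"]


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def _wc_oracle(ga, gb):
    """Brute-force per-locus evaluation of the two-population
    variance-component formulas, written independently of the library."""
    r = 2
    num = den = 0.0
    for j in range(ga.shape[1]):
        xa, xb = ga[:, j], gb[:, j]
        xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
        if len(xa) < 2 or len(xb) < 2:
            continue
        ni = np.array([len(xa), len(xb)], dtype=float)
        pi = np.array([xa.mean() / 2, xb.mean() / 2])
        hi = np.array([(xa == 1).mean(), (xb == 1).mean()])
        nbar = ni.mean()
        nc = (r * nbar - (ni**2).sum() / (r * nbar)) / (r - 1)
        pbar = (ni * pi).sum() / (r * nbar)
        if pbar in (0.0, 1.0) or nc == 0:
            continue
        s2 = (ni * (pi - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ni * hi).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


PRINTED_4PLUS4 = np.array(
    [
        # group A (4 samples)
        [0, 1, 2, 0, 1, 2, 0, 1],
        [0, 0, 1, 1, 1, 2, 0, 2],
        [1, 0, 2, 0, 0, 1, 1, 1],
        [0, 1, 1, 0, 1, 2, 0, 1],
        # group B (4 samples)
        [2, 2, 0, 1, 2, 0, 2, 0],
        [2, 1, 0, 2, 2, 0, 1, 0],
        [1, 2, 1, 2, 1, 1, 2, 1],
        [2, 2, 0, 1, 2, 0, 2, 0],
    ],
    dtype=float,
)


def test_wc_fst_matches_hand_oracle_on_printed_toy():
    t = make_table(PRINTED_4PLUS4)
    a, b = t.samples[:4], t.samples[4:]
    got = weir_cockerham_fst(t, a, b)
    want = _wc_oracle(PRINTED_4PLUS4[:4], PRINTED_4PLUS4[4:])
    assert got == pytest.approx(want, abs=1e-12)


def test_fst_symmetric_and_locus_order_invariant():
    t = make_table(PRINTED_4PLUS4)
    a, b = t.samples[:4], t.samples[4:]
    assert weir_cockerham_fst(t, a, b) == pytest.approx(weir_cockerham_fst(t, b, a))
    perm = np.random.default_rng(131).permutation(t.n_loci)
    assert weir_cockerham_fst(t.take_loci(perm), a, b) == pytest.approx(
        weir_cockerham_fst(t, a, b)
    )


def test_ratio_of_sums_not_mean_of_ratios():
    """The multi-locus convention is sum(a)/sum(a+b+c); a fixture where the
    per-locus ratios differ pins the aggregation choice."""
    t = make_table(PRINTED_4PLUS4)
    a, b = t.samples[:4], t.samples[4:]
    got = weir_cockerham_fst(t, a, b)
    per_locus = []
    for j in range(t.n_loci):
        tj = t.take_loci([j])
        ga = tj.select_samples(a).genotypes
        gb = tj.select_samples(b).genotypes
        try:
            per_locus.append(_wc_oracle(ga, gb))
        except ZeroDivisionError:
            pass
    assert got != pytest.approx(np.mean(per_locus), abs=1e-6)


def test_panmictic_groups_near_zero():
    rng = np.random.default_rng(137)
    g = hwe_dosages(40, rng.uniform(0.2, 0.8, 1000), rng)
    t = make_table(g)
    fst = weir_cockerham_fst(t, t.samples[:20], t.samples[20:])
    assert abs(fst) < 0.01


def test_opposite_fixation_approaches_one():
    g = np.vstack([np.zeros((6, 50)), np.full((6, 50), 2.0)])
    t = make_table(g)
    fst = weir_cockerham_fst(t, t.samples[:6], t.samples[6:])
    assert fst > 0.9
    assert fst == pytest.approx(_wc_oracle(g[:6], g[6:]), abs=1e-12)


def test_balding_nichols_recovery():
    rng = np.random.default_rng(139)
    ests = []
    for rep in range(8):
        anc = rng.uniform(0.1, 0.9, 1500)
        freqs = draw_region_frequencies(anc, 0.15, 2, rng)
        g = np.vstack([hwe_dosages(25, freqs[0], rng), hwe_dosages(25, freqs[1], rng)])
        t = make_table(g)
        ests.append(weir_cockerham_fst(t, t.samples[:25], t.samples[25:]))
    assert abs(np.mean(ests) - 0.15) < 0.02


def test_group_overlap_rejected():
    t = make_table(PRINTED_4PLUS4)
    with pytest.raises(ValueError):
        weir_cockerham_fst(t, t.samples[:4], t.samples[3:])


# ---------------------------------------------------------------------------
# geography


def test_identical_points_zero_distance():
    assert great_circle_distance((51.0, -115.0), (51.0, -115.0)) == 0.0


def test_antipodal_half_circumference():
    d = great_circle_distance((0.0, 0.0), (0.0, 180.0))
    assert d == pytest.approx(np.pi * EARTH_RADIUS_M, rel=1e-9)


def test_known_city_pair_within_half_percent():
    # Paris -> New York, WGS84 geodesic ~ 5,837 km; sphere agrees to <0.5%
    d = great_circle_distance((48.8566, 2.3522), (40.7128, -74.0060))
    assert d == pytest.approx(5_837_000, rel=0.005)


def test_invalid_coordinates_rejected():
    with pytest.raises(ValueError):
        great_circle_distance((95.0, 0.0), (0.0, 0.0))


def test_rousset_transform_strictly_increasing():
    xs = np.linspace(-0.2, 0.95, 50)
    ys = [rousset_distance(x) for x in xs]
    assert (np.diff(ys) > 0).all()
    with pytest.raises(ValueError):
        rousset_distance(1.0)


# ---------------------------------------------------------------------------
# isolation by distance


def _grid_fixture(slope=2e-8):
    """Colonies on a line with genetic distance proportional to meters."""
    coords = {f"C{i}": (45.0, -120.0 + i * 0.5) for i in range(6)}
    rows = []
    for i in range(6):
        for j in range(i + 1, 6):
            d = great_circle_distance(coords[f"C{i}"], coords[f"C{j}"])
            rous = slope * d
            rows.append({"colony_a": f"C{i}", "colony_b": f"C{j}", "fst": rous / (1 + rous)})
    return pd.DataFrame(rows), coords


def test_proportional_fixture_perfect_fit():
    pairs, coords = _grid_fixture()
    res = ibd_regression(pairs, coords, n_permutations=199, seed=1)
    assert res.r2 == pytest.approx(1.0, abs=1e-10)
    assert res.slope == pytest.approx(2e-8, rel=1e-6)
    assert res.mantel_p == pytest.approx(1.0 / 200.0)


def test_permutation_p_reproducible_and_stable():
    rng = np.random.default_rng(149)
    pairs, coords = _grid_fixture()
    noisy = pairs.copy()
    noisy["fst"] = noisy["fst"] * (1 + 0.3 * rng.standard_normal(len(noisy)))
    r1 = ibd_regression(noisy, coords, n_permutations=499, seed=7)
    r2 = ibd_regression(noisy, coords, n_permutations=499, seed=7)
    assert r1.mantel_p == r2.mantel_p
    r4 = ibd_regression(noisy, coords, n_permutations=999, seed=7)
    assert (r1.mantel_p < 0.05) == (r4.mantel_p < 0.05)


def test_shuffled_geography_null():
    """Genetic distances shuffled against geography: r2 ~ 0, p large."""
    rng = np.random.default_rng(151)
    pairs, coords = _grid_fixture()
    shuffled = pairs.copy()
    shuffled["fst"] = rng.permutation(shuffled["fst"].to_numpy())
    res = ibd_regression(shuffled, coords, n_permutations=499, seed=3)
    assert res.r2 < 0.35
    assert res.mantel_p > 0.05


def test_stepping_stone_simulation_positive_ibd():
    """Regions further apart are more diverged; IBD regression finds a
    positive slope with Mantel p < 0.05."""
    rng = np.random.default_rng(157)
    n_regions, per_region = 6, 4
    anc = rng.uniform(0.2, 0.8, 400)
    # stepping-stone: frequencies drift cumulatively along the chain
    freqs = [np.clip(anc.copy(), 0.02, 0.98)]
    for _ in range(n_regions - 1):
        step = draw_region_frequencies(freqs[-1], 0.03, 1, rng)[0]
        freqs.append(step)
    rows, coords, samples, blocks, meta_rows = [], {}, [], [], []
    for r in range(n_regions):
        for c in range(per_region):
            cid = f"R{r}C{c}"
            coords[cid] = (45.0 + 0.02 * c, -120.0 + 2.0 * r)
            g = hwe_dosages(8, freqs[r], rng)
            blocks.append(g)
            for w in range(8):
                sid = f"{cid}_w{w}"
                samples.append(sid)
                meta_rows.append((sid, cid, f"r{r}", *coords[cid], "colony"))
    t = make_table(np.vstack(blocks), samples=samples)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "colony", "region", "lat", "lon", "origin"]
    )
    pairs = pairwise_colony_fst(t, meta, min_workers=6)
    res = ibd_regression(pairs, coords, n_permutations=499, seed=11)
    assert res.slope > 0
    assert res.mantel_p < 0.05


def test_regional_heterozygosity_table(default_population):
    cfg, table, meta, _ = default_population
    het = regional_heterozygosity(table, meta)
    assert set(het["region"]) == set(meta["region"])
    assert het["expected_heterozygosity"].between(0, 0.6).all()
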