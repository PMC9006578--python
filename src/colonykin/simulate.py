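"""Haplodiploid colony / population simulator.

Generates diploid worker genotypes with the pedigree structure of socially
polymorphic *Formica* ants: colonies are headed by one singly-mated queen
(monogyne), one multiply-mated queen (polyandrous), two full-sister queens
(oligogynous), or several unrelated queens (polygyne).  Males are haploid,
so full sisters share their father's entire genome and are related by ~0.75.

A non-recombining "supergene" block on one chromosome carries two divergent
haplotypes, M and P.  By convention the REF allele marks the M haplotype at
the fixed-difference loci, which is what lets the supergene module orient
its MM/PP homozygote clusters.  Regional allele-frequency divergence at
background loci follows the Balding–Nichols model.  Genotyping error is
applied after the pedigree draw: allelic dropout converts true heterozygotes
into random homozygotes, then calls are masked missing at a flat rate.

Every stochastic choice flows from a single seed through
:class:`numpy.random.SeedSequence` spawning, one substream per colony, so a
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import GenotypeTable

SOCIAL_FORMS = ("monogyne", "polyandrous", "oligogynous", "polygynous")
SUPERGENE_CLASSES = ("MM", "MP", "PP")

#: Sampling-region reference coordinates (deg lat, deg lon): Alberta,
#: northern BC, southern BC, Idaho, California.
DEFAULT_REGION_COORDS = [
    (51.0, -115.0),
    (54.5, -126.0),
    (49.5, -117.5),
    (44.0, -116.0),
    (38.5, -120.0),
]

DEFAULT_SOCIAL_MIX = {
    "monogyne": 0.5,
    "polyandrous": 0.1,
    "oligogynous": 0.1,
    "polygynous": 0.3,
}

#: Queen supergene-genotype distribution per colony class.  Monogyne (and the
#: single-queen variants) default to MM queens; polygyne queens may carry any
#: genotype, which reproduces the observed pattern that multi-queen colonies
#: harbour all three worker genotypes while single-queen colonies are pure MM.
DEFAULT_QUEEN_GENOTYPES = {
    "monogyne": {"MM": 1.0},
    "polyandrous": {"MM": 1.0},
    "oligogynous": {"MM": 1.0},
    "polygynous": {"MM": 1.0 / 3, "MP": 1.0 / 3, "PP": 1.0 / 3},
}

#: Probability that a mate (haploid male) carries the P haplotype.
DEFAULT_MALE_P = {
    "monogyne": 0.0,
    "polyandrous": 0.0,
    "oligogynous": 0.0,
    "polygynous": 0.5,
}

IntOrRange = Union[int, tuple]


@dataclass
class SimConfig:
    """Study-design parameters for :func:`simulate_population`.

    Defaults emulate the sampled design the analysis expects: 5 regions x
    7 colonies x 8 workers (280 workers, 35 colonies), 316 background loci
    plus 26 supergene-window loci (342 total), moderate regional divergence,
    and low genotyping-error rates.
    """

    n_regions: int = 5
    region_coords: Optional[list] = None
    colonies_per_region: int = 7
    workers_per_colony: int = 8
    n_background_loci: int = 316
    n_supergene_loci: int = 26
    supergene_window: tuple = ("chr3", 2_000_000, 12_500_000)
    fst_regions: float = 0.2
    social_mix: dict = field(default_factory=lambda: dict(DEFAULT_SOCIAL_MIX))
    n_queens_polygyne: IntOrRange = (2, 4)
    n_mates_polyandrous: IntOrRange = (2, 4)
    p_queen_genotype_by_form: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_QUEEN_GENOTYPES.items()}
    )
    p_male_p_by_form: dict = field(default_factory=lambda: dict(DEFAULT_MALE_P))
    haplotype_divergence: float = 0.9
    dropout_rate: float = 0.02
    missing_rate: float = 0.05
    transect_per_region: int = 0
    ancestral_freq_range: tuple = (0.1, 0.9)
    background_chroms: tuple = ("chr1", "chr2", "chr4", "chr5")
    coord_jitter_deg: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_coords is None:
            base = DEFAULT_REGION_COORDS
            self.region_coords = [base[i % len(base)] for i in range(self.n_regions)]
        if len(self.region_coords) != self.n_regions:
            raise ValueError("region_coords length must equal n_regions")
        if not (0.0 <= self.fst_regions < 1.0):
            raise ValueError("fst_regions must lie in [0, 1)")
        for name, rate in (
            ("dropout_rate", self.dropout_rate),
            ("missing_rate", self.missing_rate),
            ("haplotype_divergence", self.haplotype_divergence),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        total = sum(self.social_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"social_mix proportions sum to {total}, expected 1")
        unknown = set(self.social_mix) - set(SOCIAL_FORMS)
        if unknown:
            raise ValueError(f"unknown colony classes in social_mix: {unknown}")
        chrom, start, end = self.supergene_window
        if not start < end:
            raise ValueError("supergene_window start must be < end")
        if chrom in self.background_chroms:
            raise ValueError("window chromosome cannot also host background loci")
        for form, dist in self.p_queen_genotype_by_form.items():
            s = sum(dist.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"queen genotype probabilities for {form} sum to {s}")
            if set(dist) - set(SUPERGENE_CLASSES):
                raise ValueError(f"unknown supergene class for {form}: {dist}")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "supergene_window" in d:
            c, s, e = d["supergene_window"]
            d["supergene_window"] = (str(c), int(s), int(e))
        if "region_coords" in d and d["region_coords"] is not None:
            d["region_coords"] = [tuple(map(float, xy)) for xy in d["region_coords"]]
        return cls(**d)


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated dataset.

    ``samples``: sample, colony, matriline, patriline, supergene_genotype.
    ``colonies``: colony, true_form, n_queens, n_mates.
    """

    samples: pd.DataFrame
    colonies: pd.DataFrame

    def __post_init__(self) -> None:
        known = set(self.colonies["colony"])
        orphans = set(self.samples["colony"]) - known
        if orphans:
            raise ValueError(f"samples reference unknown colonies: {sorted(orphans)}")
        mono = self.colonies[self.colonies["true_form"] == "monogyne"]
        if not ((mono["n_queens"] == 1) & (mono["n_mates"] == 1)).all():
            raise ValueError("monogyne colonies must have 1 queen and 1 mate")

    def write(self, samples_path, colonies_path) -> None:
        self.samples.to_csv(samples_path, sep="\t", index=False)
        self.colonies.to_csv(colonies_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele-frequency structure


def draw_region_frequencies(
    ancestral_freqs: np.ndarray,
    fst: float,
    n_regions: int,
    rng: Union[int, np.random.Generator],
    eps: float = 1e-4,
) -> np.ndarray:
    """Balding–Nichols per-region allele frequencies.

    Each region/locus frequency is drawn ``Beta(p(1-F)/F, (1-p)(1-F)/F)``
    around the ancestral frequency p with divergence parameter ``F``; for
    F = 0 the draw collapses to p.  Returns shape (n_regions, L), clamped to
    ``[eps, 1 - eps]``.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must lie in [0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if fst == 0.0:
        out = np.tile(p, (n_regions, 1))
    else:
        scale = (1.0 - fst) / fst
        out = rng.beta(p * scale, (1.0 - p) * scale, size=(n_regions, p.size))
    return np.clip(out, eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# pedigree machinery


@dataclass
class RegionPool:
    """Per-region gene pool the pedigree draws from."""

    bg_freqs: np.ndarray  # (L_bg,) ALT frequencies at background loci
    sg_freqs: np.ndarray  # (L_sg,) ALT frequencies at non-divergent window loci
    divergent: np.ndarray  # (L_sg,) bool, True where M/P are fixed-different


def _haplotype(cls: str, pool: RegionPool, rng: np.random.Generator) -> np.ndarray:
    """One supergene haplotype (ALT-allele indicator vector) of class M or P.

    Fixed-difference loci carry REF on M and ALT on P; the remainder are
    drawn from the regional frequencies (independently per founding
    haplotype, inherited as an unbroken block thereafter).
    """
    hap = (rng.random(pool.sg_freqs.size) < pool.sg_freqs).astype(np.int8)
    hap[pool.divergent] = 0 if cls == "M" else 1
    return hap


@dataclass
class _Queen:
    bg: np.ndarray  # (2, L_bg) maternal gametes-to-be
    sg_haps: np.ndarray  # (2, L_sg)
    sg_classes: tuple  # e.g. ("M", "P")


def _random_queen(genotype_class: str, pool: RegionPool, rng: np.random.Generator) -> _Queen:
    bg = (rng.random((2, pool.bg_freqs.size)) < pool.bg_freqs).astype(np.int8)
    classes = ("M", "M") if genotype_class == "MM" else (
        ("M", "P") if genotype_class == "MP" else ("P", "P")
    )
    haps = np.stack([_haplotype(c, pool, rng) for c in classes])
    return _Queen(bg=bg, sg_haps=haps, sg_classes=classes)


@dataclass
class _Male:
    bg: np.ndarray  # (L_bg,)
    sg_hap: np.ndarray  # (L_sg,)
    sg_class: str


def _random_male(p_P: float, pool: RegionPool, rng: np.random.Generator) -> _Male:
    cls = "P" if rng.random() < p_P else "M"
    return _Male(
        bg=(rng.random(pool.bg_freqs.size) < pool.bg_freqs).astype(np.int8),
        sg_hap=_haplotype(cls, pool, rng),
        sg_class=cls,
    )


def _daughter(queen: _Queen, male: _Male, rng: np.random.Generator):
    """Mendelian daughter: one maternal allele per background locus, one
    maternal supergene haplotype as a block, plus the father's haploid genome."""
    pick = rng.integers(0, 2, size=queen.bg.shape[1])
    maternal_bg = queen.bg[pick, np.arange(queen.bg.shape[1])]
    hap_idx = int(rng.integers(0, 2))
    maternal_sg = queen.sg_haps[hap_idx]
    sg_geno = "".join(sorted((queen.sg_classes[hap_idx], male.sg_class)))
    bg = maternal_bg + male.bg
    sg = maternal_sg + male.sg_hap
    return bg.astype(np.int8), sg.astype(np.int8), sg_geno


def _sample_count(spec: IntOrRange, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _sample_class(dist: dict, rng: np.random.Generator) -> str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys])
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


@dataclass
class ColonyResult:
    """Worker genotypes plus full pedigree truth for one colony."""

    bg: np.ndarray  # (n_workers, L_bg)
    sg: np.ndarray  # (n_workers, L_sg)
    matriline: np.ndarray  # (n_workers,) queen index per worker
    patriline: np.ndarray  # (n_workers,) father index per worker
    sg_genotype: list  # per-worker "MM"/"MP"/"PP"
    colony_class: str
    n_queens: int
    n_mates: int
    queens: list  # _Queen objects (pedigree truth, not part of the dataset)
    males: list  # _Male objects


def simulate_colony(
    colony_class: str,
    pool: RegionPool,
    config: SimConfig,
    seed: Union[int, np.random.Generator, np.random.SeedSequence],
) -> ColonyResult:
    """Simulate the workers of one colony of the given social class.

    Monogyne: one queen, one mate.  Polyandrous: one queen, 2+ mates, each
    worker's father drawn uniformly.  Oligogynous: two full-sister queens
    (daughters of one simulated grandmother and grandfather), each singly
    mated.  Polygynous: several unrelated queens, each singly mated, each
    worker's mother drawn uniformly.
    """
    if colony_class not in SOCIAL_FORMS:
        raise ValueError(f"unknown colony class {colony_class!r}")
    rng = np.random.default_rng(seed)
    qdist = config.p_queen_genotype_by_form.get(colony_class, {"MM": 1.0})
    p_male = config.p_male_p_by_form.get(colony_class, 0.0)

    queens: list[_Queen] = []
    males: list[_Male] = []
    mate_of: list[list[int]] = []  # queen index -> male indices

    if colony_class == "monogyne":
        queens.append(_random_queen(_sample_class(qdist, rng), pool, rng))
        males.append(_random_male(p_male, pool, rng))
        mate_of.append([0])
    elif colony_class == "polyandrous":
        queens.append(_random_queen(_sample_class(qdist, rng), pool, rng))
        n_mates = max(2, _sample_count(config.n_mates_polyandrous, rng))
        for m in range(n_mates):
            males.append(_random_male(p_male, pool, rng))
        mate_of.append(list(range(n_mates)))
    elif colony_class == "oligogynous":
        # two full-sister queens from a simulated grandmother x grandfather
        grandmother = _random_queen(_sample_class(qdist, rng), pool, rng)
        grandfather = _random_male(p_male, pool, rng)
        for _ in range(2):
            # build each daughter phased (maternal pick | paternal genome)
            # so her own gametes segregate correctly
            pick = rng.integers(0, 2, size=grandmother.bg.shape[1])
            maternal_bg = grandmother.bg[pick, np.arange(grandmother.bg.shape[1])]
            h = int(rng.integers(0, 2))
            q = _Queen(
                bg=np.stack([maternal_bg, grandfather.bg]),
                sg_haps=np.stack([grandmother.sg_haps[h], grandfather.sg_hap]),
                sg_classes=(grandmother.sg_classes[h], grandfather.sg_class),
            )
            queens.append(q)
            males.append(_random_male(p_male, pool, rng))
            mate_of.append([len(males) - 1])
    else:  # polygynous: unrelated queens, each singly mated
        n_queens = max(2, _sample_count(config.n_queens_polygyne, rng))
        need_p = any(
            cls != "MM" and prob > 0 for cls, prob in qdist.items()
        ) or p_male > 0
        if need_p and config.n_supergene_loci == 0:
            raise ValueError("polygyne colony requires supergene loci for P haplotypes")
        for q in range(n_queens):
            queens.append(_random_queen(_sample_class(qdist, rng), pool, rng))
            males.append(_random_male(p_male, pool, rng))
            mate_of.append([len(males) - 1])

    n = config.workers_per_colony
    bg = np.empty((n, pool.bg_freqs.size), dtype=np.int8)
    sg = np.empty((n, pool.sg_freqs.size), dtype=np.int8)
    matriline = np.empty(n, dtype=int)
    patriline = np.empty(n, dtype=int)
    sg_geno: list[str] = []
    for w in range(n):
        qi = int(rng.integers(0, len(queens)))
        fi = mate_of[qi][int(rng.integers(0, len(mate_of[qi])))]
        bg[w], sg[w], g = _daughter(queens[qi], males[fi], rng)
        matriline[w], patriline[w] = qi, fi
        sg_geno.append(g)

    return ColonyResult(
        bg=bg,
        sg=sg,
        matriline=matriline,
        patriline=patriline,
        sg_genotype=sg_geno,
        colony_class=colony_class,
        n_queens=len(queens),
        n_mates=len(males),
        queens=queens,
        males=males,
    )


# ---------------------------------------------------------------------------
# error process


def apply_dropout(genotypes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Allelic dropout: each heterozygous call becomes, with probability
    ``rate``, a homozygote for one of its two alleles (equal probability)."""
    g = genotypes.astype(float).copy()
    het = g == 1.0
    hit = het & (rng.random(g.shape) < rate)
    g[hit] = rng.integers(0, 2, size=int(hit.sum())) * 2.0
    return g


def apply_missingness(genotypes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    g = genotypes.astype(float).copy()
    g[rng.random(g.shape) < rate] = np.nan
    return g


# ---------------------------------------------------------------------------
# full population


def _locus_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Locus coordinates: background loci spread over the non-window
    chromosomes, window loci uniform inside the supergene window."""
    chrom_w, start, end = config.supergene_window
    nb = config.n_background_loci
    chroms = list(config.background_chroms)
    rows = []
    per = np.array_split(np.arange(nb), len(chroms))
    for chrom, idx in zip(chroms, per):
        pos = np.sort(rng.choice(np.arange(1, 30_000_001), size=idx.size, replace=False))
        for p in pos:
            rows.append((chrom, int(p), False))
    pos_w = np.sort(
        rng.choice(np.arange(start, end + 1), size=config.n_supergene_loci, replace=False)
    )
    for p in pos_w:
        rows.append((chrom_w, int(p), True))
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=len(rows))]
    alt = np.array([bases[(list(bases).index(r) + 1 + rng.integers(0, 3)) % 4] for r in ref])
    df = pd.DataFrame(rows, columns=["chrom", "pos", "in_window"])
    df["ref"], df["alt"] = ref, alt
    order = {c: i for i, c in enumerate(chroms + [chrom_w])}
    df = df.sort_values(["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s)
    return df.reset_index(drop=True)


def simulate_population(config: SimConfig):
    """Simulate the full sampling design.

    Returns ``(GenotypeTable, metadata DataFrame, TruthTable)``.  Colony
    classes are allocated deterministically from ``social_mix`` (largest
    remainders) within each region so the realized class census matches the
    requested proportions as closely as integer counts allow.
    """
    ss = np.random.SeedSequence(config.seed)
    n_colonies = config.n_regions * config.colonies_per_region
    # one substream per colony + one for shared structure + one for errors
    children = ss.spawn(n_colonies + 3)
    rng = np.random.default_rng(children[0])

    lo, hi = config.ancestral_freq_range
    anc_bg = rng.uniform(lo, hi, size=config.n_background_loci)
    anc_sg = rng.uniform(lo, hi, size=config.n_supergene_loci)
    n_div = int(round(config.haplotype_divergence * config.n_supergene_loci))
    divergent = np.zeros(config.n_supergene_loci, dtype=bool)
    divergent[rng.choice(config.n_supergene_loci, size=n_div, replace=False)] = True

    freq_bg = draw_region_frequencies(anc_bg, config.fst_regions, config.n_regions, rng)
    freq_sg = draw_region_frequencies(anc_sg, config.fst_regions, config.n_regions, rng)

    loci = _locus_frame(config, rng)
    bg_order = np.where(~loci["in_window"].to_numpy())[0]
    sg_order = np.where(loci["in_window"].to_numpy())[0]

    # per-region colony class allocation by largest remainders
    forms = sorted(config.social_mix, key=lambda f: SOCIAL_FORMS.index(f))
    props = np.array([config.social_mix[f] for f in forms])

    def allocate(k: int) -> list:
        raw = props * k
        base = np.floor(raw).astype(int)
        rem = k - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        out = []
        for f, c in zip(forms, base):
            out.extend([f] * c)
        return out

    sample_rows, colony_rows, meta_rows = [], [], []
    geno_blocks = []
    colony_idx = 0
    for r in range(config.n_regions):
        pool = RegionPool(bg_freqs=freq_bg[r], sg_freqs=freq_sg[r], divergent=divergent)
        classes = allocate(config.colonies_per_region)
        lat0, lon0 = config.region_coords[r]
        region = f"region{r + 1}"
        for cls in classes:
            colony_idx += 1
            cid = f"C{colony_idx:03d}"
            sub = children[colony_idx]
            res = simulate_colony(cls, pool, config, sub)
            jit = np.random.default_rng(sub).normal(0, config.coord_jitter_deg, size=2)
            lat, lon = lat0 + jit[0], lon0 + jit[1]
            geno = np.empty((res.bg.shape[0], len(loci)), dtype=float)
            geno[:, bg_order] = res.bg
            geno[:, sg_order] = res.sg
            geno_blocks.append(geno)
            for w in range(res.bg.shape[0]):
                sid = f"{cid}_w{w + 1:02d}"
                sample_rows.append((sid, cid, res.matriline[w], res.patriline[w], res.sg_genotype[w]))
                meta_rows.append((sid, cid, region, lat, lon, "colony"))
            colony_rows.append((cid, cls, res.n_queens, res.n_mates))

        # optional transect singletons: unrelated HWE individuals
        trng = np.random.default_rng(children[n_colonies + 1].spawn(config.n_regions)[r])
        for t in range(config.transect_per_region):
            sid = f"{region}_t{t + 1:02d}"
            bg = (
                (trng.random(freq_bg[r].size) < freq_bg[r]).astype(int)
                + (trng.random(freq_bg[r].size) < freq_bg[r]).astype(int)
            )
            hap1 = _haplotype("M", pool, trng)
            hap2 = _haplotype("M", pool, trng)
            sg = hap1 + hap2
            geno = np.empty((1, len(loci)), dtype=float)
            geno[:, bg_order] = bg
            geno[:, sg_order] = sg
            geno_blocks.append(geno)
            sample_rows.append((sid, "", -1, -1, "MM"))
            meta_rows.append((sid, "", region, lat0, lon0, "transect"))

    genotypes = np.vstack(geno_blocks)
    err_rng = np.random.default_rng(children[n_colonies + 2])
    genotypes = apply_dropout(genotypes, config.dropout_rate, err_rng)
    genotypes = apply_missingness(genotypes, config.missing_rate, err_rng)

    samples = [row[0] for row in sample_rows]
    table = GenotypeTable(
        samples=samples,
        loci=loci[["chrom", "pos", "ref", "alt"]],
        genotypes=genotypes,
    )
    metadata = pd.DataFrame(meta_rows, columns=["sample", "colony", "region", "lat", "lon", "origin"])
    truth = TruthTable(
        samples=pd.DataFrame(
            sample_rows,
            columns=["sample", "colony", "matriline", "patriline", "supergene_genotype"],
        ),
        colonies=pd.DataFrame(colony_rows, columns=["colony", "true_form", "n_queens", "n_mates"]),
    )
    return table, metadata, truth


def simulate_unrelated(
    n: int,
    freqs: np.ndarray,
    rng: Union[int, np.random.Generator],
    chrom: str = "chr1",
) -> GenotypeTable:
    """Unrelated diploids under Hardy–Weinberg at the given ALT frequencies.

    A calibration utility: the genomic-relationship (Ajk) statistic should
    average 0 off-diagonal and 1 on the diagonal in such a sample.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs = np.asarray(freqs, dtype=float)
    geno = (rng.random((n, freqs.size)) < freqs).astype(int) + (
        rng.random((n, freqs.size)) < freqs
    ).astype(int)
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, freqs.size + 1),
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeTable(
        samples=[f"ind{i + 1}" for i in range(n)],
        loci=loci,
        genotypes=geno.astype(float),
    )
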