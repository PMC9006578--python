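"""Pairwise relatedness / kinship estimators and per-individual inbreeding.

Four estimators are provided, all moment-based and all handling missing data
by restricting each pair to its jointly called loci:

* ``ajk`` — the genomic-relationship (GRM) statistic: expectation 0 between
  unrelated individuals of one population, 1 on the diagonal for non-inbred
  individuals.
* ``king_phi`` — the robust kinship coefficient from heterozygote
  concordance and opposite-homozygote counts; maximum 0.5 (duplicates).
* ``moments_relatedness`` — the symmetrized Queller–Goodnight
  method-of-moments relatedness (the package's diploid moments estimator).
* ``pi_hat`` — proportion of the genome shared identical-by-descent,
  from method-of-moments IBD-state probabilities given IBS counts.

All pairwise routines are vectorized as indicator-matrix products, so a few
hundred samples by a few thousand loci costs a handful of matmuls.
Allele frequencies are always taken from the full sample handed in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeTable


@dataclass
class PairwiseMatrix:
    """Symmetric matrix of pairwise estimates with per-pair locus counts.

    ``values`` is (n, n); the diagonal is NaN for estimators without a self
    form.  ``n_loci`` counts the jointly called loci behind each entry.
    Undefined estimates (zero usable loci or a zero denominator) are NaN.
    """

    samples: list
    values: np.ndarray
    n_loci: np.ndarray
    estimator: str

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle (i<j) estimates as a flat vector."""
        iu = np.triu_indices(len(self.samples), k=1)
        return self.values[iu]

    def pair(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.values[i, j])

    def submatrix(self, names) -> "PairwiseMatrix":
        idx = [self.samples.index(n) for n in names]
        return PairwiseMatrix(
            samples=list(names),
            values=self.values[np.ix_(idx, idx)],
            n_loci=self.n_loci[np.ix_(idx, idx)],
            estimator=self.estimator,
        )

    def to_long(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.samples), k=1)
        return pd.DataFrame(
            {
                "sample_a": [self.samples[i] for i in iu[0]],
                "sample_b": [self.samples[j] for j in iu[1]],
                "estimator": self.estimator,
                "value": self.values[iu],
                "n_loci": self.n_loci[iu].astype(int),
            }
        )


def _prep(table: GenotypeTable):
    g = table.genotypes
    m = ~np.isnan(g)
    p = table.alt_freqs()
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    return g[:, poly], m[:, poly], p[poly]


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def ajk(table: GenotypeTable) -> PairwiseMatrix:
    """Genomic-relationship statistic A_jk, with the self (diagonal) form.

    Off-diagonal: mean over jointly called polymorphic loci of
    ``(x_j - 2p)(x_k - 2p) / (2p(1-p))``.  Diagonal:
    ``1 + mean[(x^2 - (1+2p)x + 2p^2) / (2p(1-p))]`` over the individual's
    called loci.  ``p`` is the sample ALT frequency.
    """
    g, m, p = _prep(table)
    if p.size < 2:
        raise ValueError("ajk needs at least 2 polymorphic loci")
    denom = 2.0 * p * (1.0 - p)
    z = np.where(m, (np.nan_to_num(g) - 2.0 * p) / np.sqrt(denom), 0.0)
    mf = m.astype(float)
    counts = mf @ mf.T
    values = _safe_div(z @ z.T, counts)
    # self form
    x = np.nan_to_num(g)
    term = np.where(m, (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom, 0.0)
    own = mf.sum(axis=1)
    diag = 1.0 + _safe_div(term.sum(axis=1), own)
    np.fill_diagonal(values, diag)
    counts_i = counts.copy()
    np.fill_diagonal(counts_i, own)
    return PairwiseMatrix(list(table.samples), values, counts_i, "ajk")


def king_phi(table: GenotypeTable) -> PairwiseMatrix:
    """KING robust kinship coefficient ɸ.

    ``ɸ = (N_Aa,Aa - 2 N_AA,aa) / (N_Aa(j) + N_Aa(k))`` over loci called in
    both members, where N_Aa,Aa counts jointly heterozygous loci, N_AA,aa
    opposite homozygotes, and N_Aa(·) each member's heterozygous loci within
    the shared set.  Maximum 0.5 for identical genotypes.
    """
    g = table.genotypes
    m = (~np.isnan(g)).astype(float)
    het = (g == 1).astype(float)
    hom0 = (g == 0).astype(float)
    hom2 = (g == 2).astype(float)
    n_hh = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    n_het = het @ m.T + m @ het.T  # N_Aa(j) within shared + N_Aa(k) within shared
    values = _safe_div(n_hh - 2.0 * n_opp, n_het)
    counts = m @ m.T
    np.fill_diagonal(values, np.nan)
    return PairwiseMatrix(list(table.samples), values, counts, "king_phi")


def moments_relatedness(table: GenotypeTable) -> PairwiseMatrix:
    """Symmetrized Queller–Goodnight moments relatedness.

    Per pair, ``r = Σ_l [(x-1)(y-2p) + (y-1)(x-2p)] / Σ_l [(x-1)(x-2p) +
    (y-1)(y-2p)]`` with sums over jointly called polymorphic loci and sample
    ALT frequencies p (the biallelic-dosage form of the allele-sharing
    estimator).  Expectation: 1 for duplicates, 0.75 for haplodiploid full
    sisters, 0 for unrelated pairs.
    """
    g, m, p = _prep(table)
    if p.size < 2:
        raise ValueError("moments_relatedness needs at least 2 polymorphic loci")
    x = np.nan_to_num(g)
    a = np.where(m, x - 1.0, 0.0)
    b = np.where(m, x - 2.0 * p, 0.0)
    num = a @ b.T + b @ a.T
    ab = a * b
    mf = m.astype(float)
    den = ab @ mf.T + mf @ ab.T
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    counts = mf @ mf.T
    np.fill_diagonal(out, np.nan)
    return PairwiseMatrix(list(table.samples), out, counts, "moments")


def pi_hat(table: GenotypeTable) -> PairwiseMatrix:
    """Proportion IBD, π̂ = P(IBD=1)/2 + P(IBD=2).

    Method of moments: per pair, count loci in IBS states 0/1/2 over jointly
    called polymorphic loci, equate to the HWE expectations of those counts
    conditional on IBD state, solve the resulting triangular system for
    (P0, P1, P2), bound each to [0, 1] and renormalize.
    """
    g, m, p = _prep(table)
    if p.size < 2:
        raise ValueError("pi_hat needs at least 2 polymorphic loci")
    q = 1.0 - p
    het = np.where(m, (g == 1).astype(float), 0.0)
    hom0 = np.where(m, (g == 0).astype(float), 0.0)
    hom2 = np.where(m, (g == 2).astype(float), 0.0)
    mf = m.astype(float)
    shared = mf @ mf.T
    ibs0 = hom0 @ hom2.T + hom2 @ hom0.T
    ibs2 = het @ het.T + hom0 @ hom0.T + hom2 @ hom2.T
    ibs1 = shared - ibs0 - ibs2

    # per-locus HWE expectations conditional on IBD state
    e0_ibd0 = 2.0 * p**2 * q**2
    e1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_ibd0 = 1.0 - e0_ibd0 - e1_ibd0
    e1_ibd1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e2_ibd1 = 1.0 - e1_ibd1

    def pair_sum(e):  # Σ over jointly called loci of a per-locus expectation
        return (mf * e) @ mf.T

    s0_0 = pair_sum(e0_ibd0)
    s1_0 = pair_sum(e1_ibd0)
    s2_0 = pair_sum(e2_ibd0)
    s1_1 = pair_sum(e1_ibd1)
    s2_1 = pair_sum(e2_ibd1)

    p0 = _safe_div(ibs0, s0_0)
    p1 = _safe_div(ibs1 - p0 * s1_0, s1_1)
    p2 = _safe_div(ibs2 - p0 * s2_0 - p1 * s2_1, shared)
    with np.errstate(invalid="ignore"):
        p0 = np.clip(p0, 0.0, 1.0)
        p1 = np.clip(p1, 0.0, 1.0)
        p2 = np.clip(p2, 0.0, 1.0)
        total = p0 + p1 + p2
    ok = total > 0
    for arr in (p0, p1, p2):
        arr[ok] /= total[ok]
    values = p1 / 2.0 + p2
    np.fill_diagonal(values, np.nan)
    return PairwiseMatrix(list(table.samples), values, shared, "pi_hat")


def individual_fis(table: GenotypeTable) -> pd.DataFrame:
    """Per-individual inbreeding coefficient F from homozygosity excess.

    ``F_j = (O_hom - E_hom) / (L_j - E_hom)`` where, over the L_j loci
    called in j, O_hom counts homozygous calls and ``E_hom = Σ_i [1 -
    2 p_i (1-p_i) n_i / (n_i - 1)]`` with n_i the called allele count at
    locus i.  Negative F marks heterozygosity excess.  Returns a frame with
    columns sample, fis, n_loci, o_hom, e_hom (fis NaN when undefined).
    """
    g = table.genotypes
    m = ~np.isnan(g)
    p = table.alt_freqs()
    n_alleles = table.allele_counts().astype(float)
    poly = ~np.isnan(p) & (p > 0) & (p < 1) & (n_alleles >= 2)
    g, m, p, n_alleles = g[:, poly], m[:, poly], p[poly], n_alleles[poly]
    if p.size < 1:
        raise ValueError("individual_fis needs at least 1 polymorphic locus")
    e_site = 1.0 - 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0)
    o_hom = np.where(m & (g != 1), 1.0, 0.0).sum(axis=1)
    e_hom = (m * e_site).sum(axis=1)
    l_j = m.sum(axis=1).astype(float)
    denom = l_j - e_hom
    fis = np.full(len(table.samples), np.nan)
    ok = np.abs(denom) > 1e-12
    fis[ok] = (o_hom[ok] - e_hom[ok]) / denom[ok]
    return pd.DataFrame(
        {
            "sample": table.samples,
            "fis": fis,
            "n_loci": l_j.astype(int),
            "o_hom": o_hom.astype(int),
            "e_hom": e_hom,
        }
    )


ESTIMATORS = {
    "ajk": ajk,
    "king_phi": king_phi,
    "moments": moments_relatedness,
    "pi_hat": pi_hat,
}
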