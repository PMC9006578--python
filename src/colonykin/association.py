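"""Per-SNP linear mixed-model association with kinship control.

The phenotype is the colony's social form (0 = monogyne, 1 = polygyne)
broadcast to its workers; the non-independence of nestmates is absorbed by
a random effect with covariance proportional to the centered genomic
kinship matrix K.  The model for each SNP x is

    y = mu + x beta + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I).

K is eigendecomposed once; for each SNP the likelihood is profiled over the
variance ratio lambda = sg^2/se^2 (log-spaced grid plus bounded local
refinement), and beta is tested with a Wald F test.  With K = I the scan
reduces exactly to per-SNP ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import GenotypeTable


def mean_impute(genotypes: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-locus mean dosage."""
    g = np.asarray(genotypes, dtype=float).copy()
    mu = np.nanmean(g, axis=0)
    idx = np.where(np.isnan(g))
    g[idx] = np.take(mu, idx[1])
    return g


def centered_kinship(table: GenotypeTable) -> np.ndarray:
    """Centered genomic kinship: K = (1/L) sum_i (x_i - 2p_i)(x_i - 2p_i)^T.

    Missing dosages are mean-imputed per locus before centering; columns are
    centered but not scaled (the centered-matrix convention).  K is
    symmetric positive semi-definite by construction.
    """
    p = table.alt_freqs()
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("centered kinship needs >= 2 polymorphic loci")
    x = mean_impute(table.genotypes[:, poly])
    xc = x - x.mean(axis=0)
    return (xc @ xc.T) / xc.shape[1]


@dataclass
class LMMResult:
    """Per-locus scan results plus the genome-wide threshold."""

    table: pd.DataFrame  # chrom, pos, beta, se, wald, p, lambda
    bonferroni: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def _neg_loglik(log_lam: float, d: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    """Profile -2 log likelihood (ML) at variance ratio exp(log_lam).

    d are the eigenvalues of K; yr, xr the rotated response and design.
    """
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    xtwx = (xr * w[:, None]).T @ xr
    xtwy = (xr * w[:, None]).T @ yr
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yr - xr @ beta
    n = yr.size
    rss = float((w * resid**2).sum())
    if rss <= 0:
        return np.inf
    return n * np.log(rss / n) - np.log(w).sum()


def _fit_single(d, yr, xr, grid):
    """ML over the variance ratio, then Wald test of the last design column."""
    vals = [_neg_loglik(g, d, yr, xr) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            _neg_loglik, bounds=(lo, hi), args=(d, yr, xr), method="bounded"
        )
        log_lam = float(res.x) if res.fun <= vals[i] else grid[i]
    else:
        log_lam = grid[i]
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    xtwx = (xr * w[:, None]).T @ xr
    xtwy = (xr * w[:, None]).T @ yr
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ xtwy
    resid = yr - xr @ beta
    n, p = xr.shape
    sigma2 = float((w * resid**2).sum()) / (n - p)
    se = np.sqrt(sigma2 * xtwx_inv[-1, -1])
    b = float(beta[-1])
    if se == 0:
        return b, 0.0, np.inf, 0.0, lam
    f = (b / se) ** 2
    pval = float(stats.f.sf(f, 1, n - p))
    return b, float(se), float(f), pval, lam


def lmm_scan(
    table: GenotypeTable,
    phenotype: np.ndarray,
    K: np.ndarray,
    grid_points: int = 40,
    lambda_range: tuple = (1e-5, 1e5),
) -> LMMResult:
    """Scan every locus with the mixed model; Wald test of beta = 0.

    ``phenotype`` must be a binary 0/1 vector over ``table.samples`` (the
    colony social form, treated as quantitative).  Loci whose rotated
    design is singular (e.g. imputed-constant dosage) are skipped with a
    NaN row.  The Bonferroni threshold 0.05 / (tested loci) is attached and
    each locus flagged against it.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.size != table.n_samples:
        raise ValueError("phenotype length does not match sample count")
    uniq = np.unique(y)
    if uniq.size < 2:
        raise ValueError("phenotype is constant")
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("phenotype must be binary 0/1")
    d, u = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yr = u.T @ y
    ones_r = u.T @ np.ones(table.n_samples)
    x_all = mean_impute(table.genotypes)
    grid = np.log(np.geomspace(lambda_range[0], lambda_range[1], grid_points))

    rows = []
    n_tested = 0
    for j in range(table.n_loci):
        xj = x_all[:, j]
        chrom, pos = table.loci.iloc[j][["chrom", "pos"]]
        if np.ptp(xj) == 0:
            rows.append((chrom, pos, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        xr = np.column_stack([ones_r, u.T @ xj])
        b, se, f, pval, lam = _fit_single(d, yr, xr, grid)
        rows.append((chrom, pos, b, se, f, pval, lam))
        n_tested += 1
    df = pd.DataFrame(rows, columns=["chrom", "pos", "beta", "se", "wald", "p", "lambda"])
    if n_tested == 0:
        raise ValueError("no testable (non-constant) loci")
    threshold = 0.05 / n_tested
    df["bonferroni"] = threshold
    df["significant"] = df["p"] < threshold
    return LMMResult(table=df, bonferroni=threshold)


def social_form_phenotype(
    samples: list, metadata: pd.DataFrame, forms: pd.DataFrame
) -> tuple[list, np.ndarray]:
    """Broadcast colony social form to workers as a 0/1 phenotype.

    Returns the retained sample names and their phenotype; transect samples
    and workers of undetermined or excluded colonies are dropped.
    """
    form_of = dict(zip(forms["colony"], forms["form"]))
    meta = metadata.set_index("sample")
    keep, y = [], []
    for s in samples:
        if s not in meta.index or meta.loc[s, "origin"] != "colony":
            continue
        f = form_of.get(meta.loc[s, "colony"])
        if f == "monogyne":
            keep.append(s)
            y.append(0.0)
        elif f == "polygyne":
            keep.append(s)
            y.append(1.0)
    return keep, np.array(y)
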