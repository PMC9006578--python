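"""Supergene genotyping from the non-recombining window.

Because the window is inherited as a single Mendelian block with two
divergent haplotypes (M and P), diploids fall into exactly three classes —
MM, MP, PP — which separate as three clusters along PC1 of a standardized
genotype PCA of window loci.  The heterozygote (MP) cluster is identified
by its negative window F_IS (excess heterozygosity); of the two homozygote
clusters, the one richer in REF-allele homozygotes is labeled MM, the REF
allele standing in for the M-haplotype reference orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeTable
from .relatedness import individual_fis


@dataclass
class PCAResult:
    """Sample coordinates, locus loadings, and explained-variance shares."""

    samples: list
    coords: np.ndarray  # (n, k)
    loadings: pd.DataFrame  # loci x PCs, with chrom/pos columns
    explained: np.ndarray  # (k,) fraction of variance


def window_pca(table: GenotypeTable, n_components: int = 3) -> PCAResult:
    """Variance-standardized genotype PCA of the window loci.

    Missing dosages are mean-imputed per locus; columns are centered by
    ``2 p̂`` and scaled by ``sqrt(2 p̂ (1-p̂))``.  PC signs follow a fixed
    convention: each component is oriented so its largest-magnitude locus
    loading is positive.
    """
    if table.n_loci < 2:
        raise ValueError("window PCA needs at least 2 loci")
    if table.n_samples < 3:
        raise ValueError("window PCA needs at least 3 samples")
    p = table.alt_freqs()
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("window is monomorphic; PCA undefined")
    g = table.genotypes[:, poly]
    p = p[poly]
    loci = table.loci.loc[poly, ["chrom", "pos"]].reset_index(drop=True)
    x = np.where(np.isnan(g), 2.0 * p, g)
    z = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    k = min(n_components, min(z.shape) - 1) or 1
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    coords = u[:, :k] * s[:k]
    load = vt[:k].T  # loci x k
    for c in range(k):
        top = np.argmax(np.abs(load[:, c]))
        if load[top, c] < 0:
            load[:, c] *= -1.0
            coords[:, c] *= -1.0
    total = (s**2).sum()
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    loadings = loci.copy()
    for c in range(k):
        loadings[f"PC{c + 1}"] = load[:, c]
    return PCAResult(list(table.samples), coords, loadings, explained)


def cluster_pc1(pc1: np.ndarray) -> np.ndarray:
    """Optimal one-dimensional 3-means on PC1.

    In one dimension the k-means optimum partitions the sorted values into
    contiguous segments, so the globally optimal 3-clustering is found
    exactly by scanning the two segment boundaries (prefix-sum costs).
    Deterministic by construction; labels are ordered by cluster center
    (0 = lowest PC1).  Raises when fewer than 3 distinct values exist.
    """
    x = np.asarray(pc1, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError("PC1 has fewer than 3 distinct values; cannot form 3 clusters")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def seg_cost(i, j):  # within-segment sum of squares for xs[i:j]
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    best = (np.inf, 1, 2)
    # boundaries: segments [0:a), [a:b), [b:n)
    costs_first = np.array([seg_cost(0, a) for a in range(1, n - 1)])
    for b in range(2, n):
        tail = seg_cost(b, n)
        for a in range(1, b):
            c = costs_first[a - 1] + seg_cost(a, b) + tail
            if c < best[0]:
                best = (c, a, b)
    _, a, b = best
    labels_sorted = np.empty(n, dtype=int)
    labels_sorted[:a] = 0
    labels_sorted[a:b] = 1
    labels_sorted[b:] = 2
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def window_fis(table: GenotypeTable) -> pd.DataFrame:
    """Per-individual F_IS restricted to the window loci (same formula as
    the genome-wide individual inbreeding coefficient)."""
    return individual_fis(table)


def ref_hom_fraction(table: GenotypeTable) -> np.ndarray:
    """Per-sample fraction of called window loci homozygous for REF."""
    g = table.genotypes
    m = ~np.isnan(g)
    with np.errstate(invalid="ignore"):
        return np.where(m.sum(axis=1) > 0, (g == 0).sum(axis=1) / m.sum(axis=1), np.nan)


class OrientationError(RuntimeError):
    """Two homozygote clusters could not be told apart; manual review needed."""


def assign_genotypes(
    labels: np.ndarray,
    fis: np.ndarray,
    ref_hom: np.ndarray,
    samples: list,
    coords: np.ndarray | None = None,
) -> pd.DataFrame:
    """Map the three PC1 clusters to MM / MP / PP classes.

    The cluster with the lowest mean window F_IS is MP (heterozygotes);
    the remaining cluster with the higher mean REF-homozygosity fraction is
    MM, the other PP.  Per-sample conflicts (an MP-cluster sample with
    positive F_IS, or a homozygote-cluster sample with negative F_IS) are
    flagged, never reassigned.
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) != {0, 1, 2}:
        raise ValueError("expected exactly 3 clusters labeled 0, 1, 2")
    mean_fis = np.array([np.nanmean(fis[labels == c]) for c in range(3)])
    mp = int(np.nanargmin(mean_fis))
    rest = [c for c in range(3) if c != mp]
    mean_ref = np.array([np.nanmean(ref_hom[labels == c]) for c in rest])
    if np.isclose(mean_ref[0], mean_ref[1]):
        raise OrientationError(
            "homozygote clusters tie on reference-allele homozygosity; "
            "cannot orient MM vs PP"
        )
    mm = rest[int(np.argmax(mean_ref))]
    pp = rest[1 - int(np.argmax(mean_ref))]
    class_of = {mp: "MP", mm: "MM", pp: "PP"}
    classes = [class_of[c] for c in labels]
    flags = []
    for cls, f in zip(classes, fis):
        if np.isnan(f):
            flags.append("fis_undefined")
        elif cls == "MP" and f > 0:
            flags.append("mp_with_positive_fis")
        elif cls in ("MM", "PP") and f < 0:
            flags.append("homozygote_with_negative_fis")
        else:
            flags.append("")
    out = pd.DataFrame(
        {
            "sample": samples,
            "cluster": labels,
            "window_fis": fis,
            "ref_hom_fraction": ref_hom,
            "genotype": classes,
            "flag": flags,
        }
    )
    if coords is not None:
        for c in range(coords.shape[1]):
            out.insert(1 + c, f"PC{c + 1}", coords[:, c])
    return out


def call_supergene_genotypes(inside: GenotypeTable, n_components: int = 3) -> tuple[pd.DataFrame, PCAResult]:
    """End-to-end window genotyping: PCA -> 3-means on PC1 -> orientation."""
    pca = window_pca(inside, n_components=n_components)
    labels = cluster_pc1(pca.coords[:, 0])
    fis = window_fis(inside).set_index("sample").loc[inside.samples, "fis"].to_numpy()
    ref_hom = ref_hom_fraction(inside)
    calls = assign_genotypes(labels, fis, ref_hom, inside.samples, coords=pca.coords)
    return calls, pca


def colony_composition(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    forms: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-colony MM/MP/PP counts, ordered by region then P-haplotype frequency.

    ``forms`` (optional) is a frame with columns colony, form; colonies
    called "undetermined" are split into the second returned frame, mirroring
    their exclusion from the main composition display.
    """
    df = calls.merge(metadata[["sample", "colony", "region"]], on="sample")
    df = df[df["colony"].astype(str) != ""]
    rows = []
    for (colony, region), grp in df.groupby(["colony", "region"]):
        counts = grp["genotype"].value_counts()
        mm, mp, pp = (int(counts.get(k, 0)) for k in ("MM", "MP", "PP"))
        n = mm + mp + pp
        rows.append(
            {
                "colony": colony,
                "region": region,
                "MM": mm,
                "MP": mp,
                "PP": pp,
                "n": n,
                "p_hap_freq": (2 * pp + mp) / (2 * n) if n else np.nan,
            }
        )
    comp = pd.DataFrame(rows).sort_values(
        ["region", "p_hap_freq", "colony"], ascending=[True, True, True]
    ).reset_index(drop=True)
    if forms is not None:
        comp = comp.merge(forms[["colony", "form"]], on="colony", how="left")
        undet = comp[comp["form"] == "undetermined"].reset_index(drop=True)
        comp = comp[comp["form"] != "undetermined"].reset_index(drop=True)
        return comp, undet
    return comp, pd.DataFrame(columns=comp.columns)
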