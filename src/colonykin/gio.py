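"""VCF / metadata I/O and the sequential genotype-quality filters.

Filtering reproduces the usual RADseq command-line sequence: per-call depth
floor, per-locus missingness, minor-allele frequency, then per-sample
missingness, with a final monomorphism re-check after samples are removed.
The realized counts at every step are kept in a :class:`FilterLog` so a run
can report its own "retained loci in retained workers" line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import GenotypeTable, validate_metadata

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> GenotypeTable:
    """Read a VCF into a :class:`GenotypeTable` (ALT-dosage convention).

    Multi-allelic records and records whose ALT is not a simple SNP are
    dropped with a logged count; half-calls are treated as missing; phase
    is ignored.  Loci are returned in file order.  Per-call DP is captured
    when the FORMAT declares it.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    rows, geno_cols, depth_cols = [], [], []
    n_multi = n_half = 0
    has_depth = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        # work from raw allele indices: any negative allele (".") => missing,
        # which treats half-calls ("0/.") as missing rather than a dosage
        alleles = np.array([gt[:-1] for gt in var.genotypes], dtype=float)
        g = alleles.sum(axis=1)
        bad = (alleles < 0).any(axis=1)
        n_half += int((bad & (alleles >= 0).any(axis=1)).sum())
        g[bad] = np.nan
        geno_cols.append(g)
        try:
            dp_field = var.format("DP")
        except KeyError:
            dp_field = None
        if dp_field is not None:
            has_depth = True
            dp = dp_field.astype(float).ravel()
            dp[dp < 0] = np.nan
            depth_cols.append(dp)
        else:
            depth_cols.append(np.full(len(samples), np.nan))
    if n_multi or n_half:
        logger.info("read_vcf: dropped %d multi-allelic records, masked %d half-calls", n_multi, n_half)
    if not rows:
        raise ValueError(f"{path}: no usable bi-allelic SNP records")
    loci = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    genotypes = np.column_stack(geno_cols)
    depths = np.column_stack(depth_cols) if has_depth else None
    return GenotypeTable(samples=samples, loci=loci, genotypes=genotypes, depths=depths)


def write_vcf(table: GenotypeTable, path) -> None:
    """Write a minimal VCF 4.2 with GT (and DP when depths are present)."""
    has_dp = table.depths is not None
    fmt = "GT:DP" if has_dp else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=colonykin\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in table.loci["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, locus in table.loci.iterrows():
            fields = [
                str(locus["chrom"]),
                str(int(locus["pos"])),
                ".",
                str(locus["ref"]),
                str(locus["alt"]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for i in range(table.n_samples):
                g = table.genotypes[i, j]
                call = "./." if np.isnan(g) else gt_str[g]
                if has_dp:
                    d = table.depths[i, j]
                    call += ":" + ("." if np.isnan(d) else str(int(d)))
                fields.append(call)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample metadata (sample, colony, region, lat,
    lon[, origin]) and validate it."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "colony": str, "region": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterLog:
    """Realized counts at each sequential filter step."""

    steps: list = field(default_factory=list)

    def record(self, step: str, n_samples: int, n_loci: int, removed: int) -> None:
        self.steps.append(
            {"step": step, "n_samples": n_samples, "n_loci": n_loci, "removed": removed}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class EmptyFilterResult(ValueError):
    """All loci or all samples removed; carries the stage that emptied the set."""

    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"filtering removed everything at stage {stage!r}")


def filter_genotypes(
    table: GenotypeTable,
    min_depth: int = 7,
    max_locus_missing: float = 0.2,
    min_maf: float = 0.05,
    max_sample_missing: float = 0.2,
) -> tuple[GenotypeTable, FilterLog]:
    """Apply the depth / locus-missingness / MAF / sample-missingness filters.

    Order is fixed: (1) mask calls with depth below ``min_depth`` (skipped
    when the table has no depths); (2) drop loci missing in more than
    ``max_locus_missing`` of samples; (3) drop loci with minor-allele
    frequency below ``min_maf`` over non-missing calls; (4) drop samples
    missing at more than ``max_sample_missing`` of retained loci; (5) drop
    loci left monomorphic by sample removal.  Missingness fractions are
    relative to the currently retained set at each step.
    """
    for name, v in (
        ("max_locus_missing", max_locus_missing),
        ("min_maf", min_maf),
        ("max_sample_missing", max_sample_missing),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if min_maf > 0.5:
        raise ValueError("min_maf above 0.5 removes every locus by definition")

    log = FilterLog()
    t = table.copy()
    log.record("input", t.n_samples, t.n_loci, 0)

    if t.depths is not None:
        low = ~np.isnan(t.depths) & (t.depths < min_depth)
        g = t.genotypes.copy()
        g[low] = np.nan
        t.genotypes = g
        log.record("depth_mask", t.n_samples, t.n_loci, int(low.sum()))

    keep = t.locus_missing_fraction() <= max_locus_missing
    removed = int((~keep).sum())
    t = t.take_loci(np.where(keep)[0])
    log.record("locus_missingness", t.n_samples, t.n_loci, removed)
    if t.n_loci == 0:
        raise EmptyFilterResult("locus_missingness")

    p = t.alt_freqs()
    maf = np.minimum(p, 1.0 - p)
    keep = ~np.isnan(maf) & (maf >= min_maf)
    removed = int((~keep).sum())
    t = t.take_loci(np.where(keep)[0])
    log.record("maf", t.n_samples, t.n_loci, removed)
    if t.n_loci == 0:
        raise EmptyFilterResult("maf")

    keep_s = t.sample_missing_fraction() <= max_sample_missing
    removed = int((~keep_s).sum())
    t = t.take_samples(np.where(keep_s)[0])
    log.record("sample_missingness", t.n_samples, t.n_loci, removed)
    if t.n_samples == 0:
        raise EmptyFilterResult("sample_missingness")

    p = t.alt_freqs()
    keep = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    removed = int((~keep).sum())
    t = t.take_loci(np.where(keep)[0])
    log.record("monomorphic_recheck", t.n_samples, t.n_loci, removed)
    if t.n_loci == 0:
        raise EmptyFilterResult("monomorphic_recheck")

    return t, log


# ---------------------------------------------------------------------------
# supergene-window split


def split_by_region_mask(
    table: GenotypeTable, window: tuple
) -> tuple[GenotypeTable, GenotypeTable]:
    """Split loci by the supergene window (chromosome, start, end; 1-based,
    inclusive on both ends).

    ``inside`` holds window loci; ``outside`` holds loci NOT on the window
    chromosome at all — the social-structure and popgen analyses drop the
    entire chromosome, so off-window loci on it appear in neither output.
    Both tables carry a provenance flag in ``region_mask``.
    """
    chrom, start, end = window
    chroms = table.loci["chrom"].to_numpy()
    pos = table.loci["pos"].to_numpy()
    on_chrom = chroms == chrom
    in_win = on_chrom & (pos >= start) & (pos <= end)
    inside = table.take_loci(np.where(in_win)[0])
    outside = table.take_loci(np.where(~on_chrom)[0])
    inside.region_mask = "inside"
    outside.region_mask = "outside"
    return inside, outside
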