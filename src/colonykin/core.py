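"""Core in-memory containers shared by every analysis stage.

The central object is :class:`GenotypeTable`: a diploid dosage matrix
(individuals x bi-allelic loci, dosage = number of ALT alleles, NaN for a
missing call) together with per-locus coordinates and optional read depths.
Sample metadata (colony, region, coordinates) travels separately as a
:class:`pandas.DataFrame` validated by :func:`validate_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]
METADATA_COLUMNS = ["sample", "colony", "region", "lat", "lon", "origin"]


@dataclass
class GenotypeTable:
    """Diploid ALT-dosage matrix with locus annotations.

    Parameters
    ----------
    samples
        Ordered sample identifiers (length n).
    loci
        DataFrame with columns ``chrom, pos, ref, alt``; positions are
        1-based and strictly increasing within a chromosome.
    genotypes
        Float array of shape (n, L); values in {0, 1, 2} or NaN (missing).
    depths
        Optional per-call read depth, same shape as ``genotypes``.
    region_mask
        Provenance flag set by :func:`colonykin.gio.split_by_region_mask`:
        ``"inside"`` (supergene window loci), ``"outside"`` (loci off the
        window chromosome entirely), or None (unsplit).
    """

    samples: list[str]
    loci: pd.DataFrame
    genotypes: np.ndarray
    depths: Optional[np.ndarray] = None
    region_mask: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.loci = self.loci.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"loci table lacks columns {missing_cols}")
        ok = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype dosages must be 0, 1, 2 or NaN")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=float)
            if self.depths.shape != self.genotypes.shape:
                raise ValueError("depths shape does not match genotypes")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) array, True where the call is missing."""
        return np.isnan(self.genotypes)

    def called_mask(self) -> np.ndarray:
        return ~self.missing_mask()

    # -- derived per-locus quantities -----------------------------------
    def alt_freqs(self) -> np.ndarray:
        """ALT allele frequency per locus over non-missing calls (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def allele_counts(self) -> np.ndarray:
        """Number of called alleles (2 x called genotypes) per locus."""
        return 2 * self.called_mask().sum(axis=0)

    def locus_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    # -- subsetting ------------------------------------------------------
    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            loci=self.loci,
            genotypes=self.genotypes[idx],
            depths=None if self.depths is None else self.depths[idx],
        )

    def take_loci(self, idx: Sequence[int] | np.ndarray) -> "GenotypeTable":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            samples=self.samples,
            loci=self.loci.iloc[idx],
            genotypes=self.genotypes[:, idx],
            depths=None if self.depths is None else self.depths[:, idx],
        )

    def select_samples(self, names: Sequence[str]) -> "GenotypeTable":
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            idx = [pos[n] for n in names]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in table") from None
        return self.take_samples(idx)

    def copy(self) -> "GenotypeTable":
        return replace(
            self,
            samples=list(self.samples),
            loci=self.loci.copy(),
            genotypes=self.genotypes.copy(),
            depths=None if self.depths is None else self.depths.copy(),
        )


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check a sample metadata frame and return it with canonical columns.

    Required columns: sample, colony, region, lat, lon; ``origin``
    (``colony`` vs ``transect``) is filled with ``colony`` when absent.
    """
    meta = meta.copy()
    if "origin" not in meta.columns:
        meta["origin"] = "colony"
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata lacks columns {missing}")
    if meta["sample"].duplicated().any():
        dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicated sample ids in metadata: {dups}")
    lat = meta["lat"].astype(float)
    lon = meta["lon"].astype(float)
    if not ((lat.abs() <= 90).all() and (lon.abs() <= 180).all()):
        raise ValueError("latitude/longitude outside valid ranges")
    return meta[METADATA_COLUMNS]
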