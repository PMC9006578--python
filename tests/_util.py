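"""Small construction helpers shared across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from colonykin.core import GenotypeTable


def make_table(
    dosages,
    chrom: str = "chr1",
    samples=None,
    positions=None,
    ref="A",
    alt="T",
    depths=None,
) -> GenotypeTable:
    """GenotypeTable from a plain dosage matrix (rows = samples)."""
    g = np.asarray(dosages, dtype=float)
    n, L = g.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    positions = positions if positions is not None else np.arange(1, L + 1) * 100
    loci = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": ref, "alt": alt}
    )
    return GenotypeTable(samples=samples, loci=loci, genotypes=g, depths=depths)


def hwe_dosages(n: int, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unrelated diploid dosages under Hardy-Weinberg."""
    freqs = np.asarray(freqs)
    return (
        (rng.random((n, freqs.size)) < freqs).astype(float)
        + (rng.random((n, freqs.size)) < freqs).astype(float)
    )
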