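"""Colony-level statistics and the consensus social-form classifier.

Three independent lines of evidence are computed per colony from loci
outside the supergene chromosome:

1. opposing homozygosity — the number of loci at which both homozygote
   classes occur among nestmates, which is impossible (bar genotyping error)
   for daughters of one singly-mated queen;
2. mean pairwise relatedness — haplodiploid full sisters sit near 0.75,
   workers of unrelated queens near 0;
3. an inferred matriline count from single-linkage clustering of the
   pairwise relatedness matrix.

Each line casts a monogyne/polygyne vote; unanimous votes give the call and
any disagreement (or a value inside the inner, ambiguous band) yields
"undetermined" — colonies are never forced into a form the evidence does
not support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import GenotypeTable
from .relatedness import ESTIMATORS, PairwiseMatrix

MONOGYNE, POLYGYNE, UNDETERMINED = "monogyne", "polygyne", "undetermined"


@dataclass
class ClassifierThresholds:
    """Vote boundaries for the consensus classifier.

    Opposing-homozygosity cuts are fractions of the locus count: at or below
    ``oh_mono_max`` votes monogyne, at or above ``oh_poly_min`` votes
    polygyne, between them the vote is ambiguous.  Allelic dropout fakes
    opposing homozygosity in true monogyne colonies at a per-locus rate of
    roughly (dropout rate) x (share of queen-heterozygous loci), about 2%
    of loci at the simulator defaults, so the monogyne cut sits several
    Poisson standard deviations above that noise floor while staying well
    under the ~13% typical of two unrelated queens.  Relatedness cuts come
    from pedigree expectations: a monogyne colony of full sisters averages
    r = 0.75, while the most monogyne-looking multi-queen sample — a 7:1
    split over two unrelated matrilines — averages 21/28 x 0.75 = 0.5625;
    the cuts bracket the gap between those two values.
    """

    oh_mono_max: float = 0.05
    oh_poly_min: float = 0.08
    r_mono_min: float = 0.65
    r_poly_max: float = 0.60
    matriline_threshold: float = 0.375
    min_workers: int = 6
    voting_estimator: str = "moments"


def opposing_homozygosity(genotypes: np.ndarray) -> int:
    """Count loci at which both homozygote classes occur among the workers.

    ``genotypes`` is a (workers x loci) dosage matrix; missing calls are
    ignored.  Requires at least two workers.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("opposing homozygosity needs >= 2 workers")
    has0 = np.nansum(g == 0, axis=0) > 0
    has2 = np.nansum(g == 2, axis=0) > 0
    return int((has0 & has2).sum())


def matriline_partition(
    rel: PairwiseMatrix | np.ndarray, threshold: float = 0.375
) -> tuple[int, np.ndarray]:
    """Partition workers into putative matrilines.

    Single-linkage agglomeration on the pairwise relatedness matrix:
    clusters keep merging while the maximum between-cluster relatedness is
    at or above ``threshold`` (equivalently, connected components of the
    graph with edges where r >= threshold).  Undefined pairs count as below
    threshold.  Returns (cluster count, labels).
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    values = rel.values if isinstance(rel, PairwiseMatrix) else np.asarray(rel, dtype=float)
    n = values.shape[0]
    if n == 1:
        return 1, np.zeros(1, dtype=int)
    sim = values.copy()
    sim = np.where(np.isnan(sim), -np.inf, sim)  # undefined pairs never merge
    sim = np.maximum(sim, sim.T)
    # single linkage stops exactly when no between-cluster pair reaches the
    # threshold, i.e. clusters are the connected components of (r >= t)
    adj = csr_matrix(sim >= threshold)
    n_comp, labels = connected_components(adj, directed=False)
    # relabel components in order of first appearance for determinism
    order = {}
    for lab in labels:
        order.setdefault(lab, len(order))
    labels = np.array([order[lab] for lab in labels])
    return int(n_comp), labels


@dataclass
class ColonyReport:
    """Per-colony evidence and the consensus call."""

    colony: str
    n_workers: int
    n_loci: int
    opposing_homozygosity: int
    mean_relatedness: dict
    matriline_count: int
    votes: dict
    form: str
    excluded: bool = False
    exclusion_reason: str = ""


def _vote_oh(oh_frac: float, th: ClassifierThresholds) -> str:
    if oh_frac <= th.oh_mono_max:
        return MONOGYNE
    if oh_frac >= th.oh_poly_min:
        return POLYGYNE
    return UNDETERMINED


def _vote_r(r: float, th: ClassifierThresholds) -> str:
    if np.isnan(r):
        return UNDETERMINED
    if r >= th.r_mono_min:
        return MONOGYNE
    if r <= th.r_poly_max:
        return POLYGYNE
    return UNDETERMINED


def classify_social_form(
    oh: int,
    n_loci: int,
    mean_r: float,
    matriline_count: int,
    thresholds: ClassifierThresholds | None = None,
) -> tuple[str, dict]:
    """Consensus monogyne/polygyne/undetermined call from three votes."""
    th = thresholds or ClassifierThresholds()
    votes = {
        "opposing_homozygosity": _vote_oh(oh / n_loci if n_loci else np.nan, th),
        "relatedness": _vote_r(mean_r, th),
        "matrilines": MONOGYNE if matriline_count == 1 else POLYGYNE,
    }
    distinct = set(votes.values())
    form = distinct.pop() if len(distinct) == 1 and UNDETERMINED not in distinct else UNDETERMINED
    return form, votes


def colony_reports(
    table: GenotypeTable,
    metadata: pd.DataFrame,
    thresholds: ClassifierThresholds | None = None,
    estimators: tuple = ("moments", "ajk", "king_phi", "pi_hat"),
) -> list[ColonyReport]:
    """Full colony-level analysis on a chromosome-masked genotype table.

    ``table`` must be the *outside* half of the supergene split (enforced
    via its provenance flag) so the social-structure evidence is
    independent of the supergene itself.  Relatedness matrices are computed
    on the whole sample (frequencies from everyone) then subset per colony.
    """
    th = thresholds or ClassifierThresholds()
    if table.region_mask != "outside":
        raise ValueError(
            "colony_reports requires the outside-window table from split_by_region_mask"
        )
    mats = {name: ESTIMATORS[name](table) for name in estimators}
    voting = mats[th.voting_estimator]

    reports = []
    meta = metadata[metadata["origin"] == "colony"]
    for colony, members in meta.groupby("colony")["sample"]:
        names = [s for s in members if s in table.samples]
        if not names:
            continue
        if len(names) < th.min_workers:
            reports.append(
                ColonyReport(
                    colony=colony,
                    n_workers=len(names),
                    n_loci=table.n_loci,
                    opposing_homozygosity=-1,
                    mean_relatedness={},
                    matriline_count=-1,
                    votes={},
                    form=UNDETERMINED,
                    excluded=True,
                    exclusion_reason=f"fewer than {th.min_workers} workers",
                )
            )
            continue
        sub = table.select_samples(names)
        oh = opposing_homozygosity(sub.genotypes)
        mean_r = {}
        for name, mat in mats.items():
            vals = mat.submatrix(names).off_diagonal()
            mean_r[name] = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        n_mat, _ = matriline_partition(voting.submatrix(names), th.matriline_threshold)
        form, votes = classify_social_form(
            oh, table.n_loci, mean_r[th.voting_estimator], n_mat, th
        )
        reports.append(
            ColonyReport(
                colony=colony,
                n_workers=len(names),
                n_loci=table.n_loci,
                opposing_homozygosity=oh,
                mean_relatedness=mean_r,
                matriline_count=n_mat,
                votes=votes,
                form=form,
            )
        )
    return reports


def reports_to_frame(reports: list[ColonyReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "colony": r.colony,
            "n_workers": r.n_workers,
            "n_loci": r.n_loci,
            "opposing_homozygosity": r.opposing_homozygosity,
            "matriline_count": r.matriline_count,
            "form": r.form,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason,
        }
        for name, v in r.mean_relatedness.items():
            row[f"mean_r_{name}"] = v
        for axis, v in r.votes.items():
            row[f"vote_{axis}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
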