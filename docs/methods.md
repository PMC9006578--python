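# Methods

`colonykin` infers the social organization of ant colonies — how many
queens produced the sampled workers — from a SNP genotype matrix, assigns
each worker a supergene genotype from a non-recombining chromosomal window,
and characterizes the population structure of the sample. Every stage is
paired with a haplodiploid pedigree simulator that generates data with the
exact structure the inference assumes, so the whole pipeline can be
validated against known truth without any sequence data.

## The biological model

Ants are haplodiploid: males develop from unfertilized eggs and are
haploid, females are diploid. A daughter receives one Mendelian-sampled
allele from her mother and her father's *entire* haploid genome, so full
sisters share on average 3/4 of their genome (relatedness r = 0.75), more
than mother and daughter (r = 0.5). Colonies come in four pedigree classes:

| class        | queens                 | mates per queen | worker mix                     |
|--------------|------------------------|-----------------|--------------------------------|
| monogyne     | 1                      | 1               | full sisters (r = 0.75)        |
| polyandrous  | 1                      | 2–4             | full + paternal half sisters   |
| oligogynous  | 2 full sisters         | 1 each          | full sisters + cousins         |
| polygynous   | 2–4 unrelated          | 1 each          | full sisters + non-relatives   |

A window on chromosome 3 (2–12.5 Mbp by default) is inherited as a single
non-recombining block with two divergent haplotypes, M and P. By
convention the REF allele marks the M haplotype at the fixed-difference
loci; diploids therefore fall into exactly three window genotypes, MM, MP
and PP.

## Colony-level inference

All colony statistics use only loci **off** the window chromosome (the
entire chromosome is excluded, not just the window), keeping the social
inference independent of the supergene itself. Three lines of evidence are
computed per colony:

1. **Opposing homozygosity (OH)** — the number of loci at which both
   homozygote classes appear among nestmates. One diploid mother and one
   haploid father cannot produce both homozygotes at a bi-allelic locus, so
   OH is exactly 0 for an error-free monogyne colony and grows with the
   number of parents.
2. **Mean pairwise relatedness** among nestmates (the moments estimator is
   the voting axis; Ajk, KING ɸ and π̂ are reported alongside).
3. **Matriline count** from single-linkage clustering of the pairwise
   relatedness matrix: clusters merge while any between-cluster pair has
   r ≥ 0.375 (implemented as connected components of the thresholded
   graph, which is what single linkage stopped at that similarity is).
   0.375 is the midpoint of full-sister (0.75) and unrelated (0).

Each line casts a monogyne/polygyne vote; a unanimous vote gives the call
and anything else gives "undetermined" — a colony is never forced into a
class its evidence conflicts on.

### Vote thresholds (calibrated on the simulator, configurable)

* `oh_mono_max = 0.05`, `oh_poly_min = 0.08` (fractions of the locus
  count). Allelic dropout fakes opposing homozygosity in true monogyne
  colonies at a per-locus rate of roughly dropout × (share of
  queen-heterozygous loci) ≈ 2% of loci at the default error rates; the
  monogyne cut sits several Poisson standard deviations above that noise
  floor, while two unrelated queens typically oppose at ~13% of loci.
* `r_mono_min = 0.65`, `r_poly_max = 0.60`. These bracket the gap between
  the monogyne expectation (0.75) and the most monogyne-looking
  multi-queen sample, a 7:1 split over two matrilines with expected mean
  r = 21/28 × 0.75 = 0.5625.
* Colonies with fewer than 6 workers are excluded from classification.

A pedigree detail worth recording: workers of two full-sister queens are
cousins through their mothers with relatedness 2 × (1/4) × ɸ(sisters)
= 3/16 ≈ 0.19 (not 0.375, which is the aunt–niece value). The simulation
oracle confirms 3/16; such colonies usually split into two matrilines while
their OH and mean r fall in the ambiguous bands, which is why oligogyne
colonies surface as "undetermined".

## Relatedness estimators

All four estimators use allele frequencies from the full filtered sample
and restrict each pair to jointly called loci; no imputation.

* **Ajk** (genomic relationship): off-diagonal
  `mean[(x_j − 2p)(x_k − 2p)/(2p(1−p))]`; diagonal
  `1 + mean[(x² − (1+2p)x + 2p²)/(2p(1−p))]`. Expectation 0 between
  unrelated members of one population, 1 on the diagonal.
* **KING ɸ**: `(N_Aa,Aa − 2 N_AA,aa)/(N_Aa(j) + N_Aa(k))`; maximum 0.5.
* **Moments relatedness**: the symmetrized Queller–Goodnight form,
  `r = Σ[(x−1)(y−2p) + (y−1)(x−2p)] / Σ[(x−1)(x−2p) + (y−1)(y−2p)]`.
  This is the package's diploid method-of-moments estimator and the
  classifier's voting axis.
* **π̂**: method-of-moments IBD-state probabilities from IBS counts under
  HWE expectations, bounded to [0,1] and renormalized; π̂ = P1/2 + P2.
  The bounding step truncates sampling noise asymmetrically, so the null
  mean carries a small positive bias (~0.04 at 1000 loci, shrinking as
  1/√L); pedigree means (e.g. 0.75 for full sisters) are unaffected.

Per-individual inbreeding uses
`F = (O_hom − E_hom)/(L − E_hom)` with the small-sample factor n/(n−1) in
the expected homozygosity, so heterozygosity excess gives F < 0.

Because frequencies come from the pooled sample, pooling diverged regions
depresses between-region estimates below zero and inflates within-region
(and within-colony) estimates — a known property of frequency-referenced
estimators that the test suite asserts rather than hides. Classifier
accuracy is therefore quantified on a single-region simulation; on the
default five-region design the inflation moves some polygyne colonies into
the ambiguous relatedness band (they surface as "undetermined", never as
monogyne).

## Supergene genotyping

Window loci are mean-imputed, centered by 2p̂ and scaled by √(2p̂(1−p̂)),
and decomposed by SVD; PC signs are fixed by orienting each component so
its largest-magnitude locus loading is positive. PC1 separates the three
window genotypes; the three clusters are found by exact one-dimensional
3-means (in 1-D the k-means optimum is a contiguous partition of the
sorted values, so the two boundaries are scanned exhaustively —
deterministic and globally optimal, where a Lloyd iteration seeded at
min/median/max collapses whenever one genotype class holds a majority).
The cluster with the lowest mean window F_IS is MP (heterozygotes); of the
two homozygote clusters, the one richer in REF-allele homozygotes is MM.
Per-sample conflicts (an MP-cluster sample with positive F_IS, or the
reverse) are flagged, never reassigned. In a reference-free run the MM/PP
labels are only as meaningful as the REF orientation of the input VCF.

## Association scan

Phenotype is the colony social form (0 = monogyne, 1 = polygyne) broadcast
to workers and treated as quantitative. Per SNP the model
`y = μ + xβ + u + ε`, `u ~ N(0, σ_g² K)`, `ε ~ N(0, σ_e² I)` uses the
centered genomic kinship `K = (1/L) Σ (x_i − 2p_i)(x_i − 2p_i)ᵀ`
(mean-imputed, centered, unscaled). K is eigendecomposed once; the
likelihood is profiled over λ = σ_g²/σ_e² by maximum likelihood on a
40-point log grid over [1e-5, 1e5] with bounded local refinement, and β is
tested with a Wald F(1, n−2) test using the GLS residual variance on n−2
degrees of freedom — with K = I the scan is algebraically identical to
per-SNP ordinary least squares, which pins the implementation. The
Bonferroni threshold is 0.05 / (tested loci).

Two structural limits of this design, both reproduced by the simulator,
are documented rather than patched:

* When the sample count exceeds the locus count, K̂ is rank-deficient and
  boundary-λ fits can regress on null-space noise, producing off-window
  false positives. Power simulations therefore use a background panel
  larger than the sample (2000 loci for 240 workers).
* Under the default queen-genotype pattern, polygyne colonies also contain
  MM workers; within-colony genotype variation against a colony-constant
  phenotype is evidence *against* a per-worker genotype effect, and the
  mixed model correctly discounts it. The power/specificity check
  therefore simulates a fully penetrant supergene (polygyne queens MP/PP
  with P-haplotype mates — the alternative queen-genotype pattern the
  configuration exposes); under the default pattern the scan finds at most
  marginal hits, which mirrors the weak genome-wide signal expected for
  this architecture.

## Population structure

* **Expected heterozygosity** per region: mean over variable sites of
  `2p̂(1−p̂)·n/(n−1)`, computed on one least-missing worker per colony
  plus all transect samples so family structure does not depress it.
* **F_ST**: Weir–Cockerham two-population variance components (a, b, c)
  with the observed-heterozygosity correction, aggregated as
  Σa / Σ(a+b+c) (ratio of sums, the standard multi-locus convention).
  Negative estimates are reported unclipped.
* **Isolation by distance**: OLS of Rousset's F_ST/(1−F_ST) on
  great-circle distance in meters (haversine, sphere radius 6,371,000 m;
  sub-percent sphere-vs-ellipsoid error is irrelevant at meter-to-2000-km
  scales). Significance by a one-sided Mantel permutation (colony labels
  of the genetic matrix permuted jointly over rows and columns), with the
  reported p lower-bounded by 1/(n_permutations + 1). Pairwise distances
  are not independent, so OLS theory p-values would be anticonservative.

## The simulator

`SimConfig` defaults emulate the sampling design the analysis expects: 5
regions × 7 colonies × 8 workers = 280 workers in 35 colonies; 316
background loci spread over four chromosomes plus 26 supergene loci inside
chr3:2,000,000–12,500,000 (342 total); regional divergence by the
Balding–Nichols model (`Beta(p(1−F)/F, (1−p)(1−F)/F)`, F = 0.2); ancestral
frequencies uniform on (0.1, 0.9); haplotype divergence 0.9 (fraction of
window loci fixed-different between M and P); colony class mix 50%
monogyne / 30% polygynous / 10% polyandrous / 10% oligogynous; polygyne
queen count and polyandrous mate count uniform on 2–4 (the mate number is
a free choice — field estimates for this system are not published);
allelic dropout 0.02 (a true heterozygote becomes a random homozygote);
per-call missingness 0.05. Monogyne, polyandrous and oligogynous queens
are MM with M mates; polygyne queens draw uniformly from {MM, MP, PP} with
half their mates carrying P, which reproduces the pattern that single-queen
colonies are pure MM while multi-queen colonies mix all three genotypes.
Everything above is a config field.

Randomness flows from one `SeedSequence` with one spawned substream per
colony plus dedicated substreams for shared structure and the error
process, so outputs are byte-identical given a seed.

What the simulator does **not** emulate: linkage among background loci,
recombination maps, selection, queen turnover, batch effects,
depth-dependent genotype quality (depths are optional and flat), or
reference-bias in allele calling. Tests passing on these simulations
therefore validate the estimators and the decision logic under the stated
pedigree and error model, not robustness to artifacts real RADseq data may
carry.

## Numerical conventions and edge cases

* Dosage counts the ALT allele; VCF positions are 1-based; the window is
  inclusive on both ends.
* Filters run in a fixed order (depth mask → locus missingness → MAF →
  sample missingness → monomorphism re-check), each threshold interpreted
  against the currently retained set; the realized counts at every step
  are logged. Filtering is idempotent.
* Pairs with no shared loci, zero estimator denominators, monomorphic
  windows, and sub-3-cluster PC1 configurations raise or flag rather than
  return silent numbers.
* Problem sizes in the test and acceptance runs (200-colony classifier
  check, 2000-locus calibration scans, 20-replicate F_ST recovery,
  199–499 Mantel permutations) were chosen as the smallest sizes at which
  the asserted expectations are comfortably inside Monte-Carlo error.
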