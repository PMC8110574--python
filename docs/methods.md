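# Methods

This note documents the models, conventions, and numerical choices behind
syntevo, and what the synthetic-data validation does and does not show.

## Coordinates and gene ranks

Internally all intervals are 0-based half-open; GFF3 I/O converts to and
from 1-based inclusive. Every gene carries a per-chromosome *rank*: its
index along the chromosome ordered by ascending start (ties broken by end,
then gene id), counting one primary model per gene. Ranks are the
coordinate system of all collinearity and radius rules — block gaps, DBSCAN
radii, extension and culling radii are all measured in gene ranks, which
makes the pipeline insensitive to intergenic-length variation. Features are
assigned to per-megabase windows by start position only, so window counts
conserve totals.

## Synteny pipeline

The pipeline has six stages, each a pure function:

1. **Cull** — self-hits removed; bit score < 50 dropped (strictly less);
   per query gene and target genome the top `2 x ploidy` hits survive
   (a haploid assembly standing for a diploid keeps 2 per genome, matching
   the top-two-per-haplotype convention).
2. **Pairwise orthogroups** — for each genome pair, hits below 50% of
   either endpoint's best inter-genome score are discarded and connected
   components of the remaining graph become orthogroups. This is a
   deterministic, dependency-free clustering; it plays the role a
   graph-clustering orthology tool would, and its granularity is controlled
   by `best_score_fraction`.
3. **Chaining** — anchors (orthogroup-consistent hits placed in rank
   space) are chained by iterated dynamic programming into runs strictly
   monotone in both ranks, in either orientation. Chain score is the anchor
   count; ties prefer the smaller total rank gap, then the smaller starting
   rank, then collinear orientation — all deterministic. Consecutive
   anchors may be at most `5 x 0.5 x MBS` ranks apart (25 at the default
   MBS = 10) on both chromosomes; chains shorter than MBS are discarded. An
   alternative reading of the gap rule (a cap on the number of gapped steps
   per block rather than on the per-step gap) is selectable via
   `SyntenyParams.gap_rule`; the per-step rule is the default because it is
   local, deterministic, and reproduces the expected block splits.
4. **Density pruning** — DBSCAN over each block's anchors in 2-D rank
   space with eps = `5 x MBS` and `min_pts = MBS` (the point itself
   counts), Chebyshev metric. Chebyshev was chosen because it matches the
   per-axis gap semantics of chaining; Euclidean is available via
   configuration. DBSCAN's border-point assignment is order-dependent in
   general, so border points are re-assigned to their nearest core point,
   making the output independent of library internals (and testable
   against a direct quadratic implementation).
5. **Completion and extension** — pairwise orthogroups sharing genes are
   merged by transitive closure into multi-genome orthogroups (idempotent);
   score-passing hits within a 100-gene-rank radius of any block rejoin the
   anchor pool, orthogroup identity notwithstanding, and chaining plus
   pruning re-run. This refills gaps left by orthogroup granularity.
6. **Classification** — hits with both endpoints within 50 gene ranks of a
   block interval on their own genome/chromosome are labelled: same
   orthogroup and different genomes → ortholog; same genome → paralog;
   no orthogroup but score ≥ 50 and ≥ 50% of that gene-by-genome best →
   un-clustered homolog; otherwise dropped.

Intra-genome (paralog-block) runs exclude self-hits and pairs within 5
ranks on the same chromosome before chaining, so tandem arrays do not
masquerade as duplicated segments.

Reporting re-filters blocks to ≥ 25 genes (configurable) and prints, per
chromosome: total genes, genes in blocks, percent in blocks (one decimal),
block count, genes in the largest block, and the percent captured by it.

## Ks estimation

The estimator is Nei–Gojobori (1986) with Jukes–Cantor correction, chosen
over a maximum-likelihood codon model because it is self-contained, fast,
and exactly checkable against a brute-force per-codon oracle; peak-location
analyses (divergence dating, WGD detection) depend on relative mode
positions, for which NG86 is adequate. A hook exists to plug in another
estimator.

Conventions, fixed so the estimator is well defined:

- Synonymous site fractions count single-base changes that preserve the
  amino acid; changes creating a stop codon count as nonsynonymous, so
  S + N = 3 exactly per codon.
- Observed differences are averaged over all mutational pathways between
  the two codons; pathways through stop codons are excluded, falling back
  to all pathways in the rare case every ordering is blocked.
- Columns with gaps or ambiguous bases are skipped; an internal stop in a
  compared column is an error.
- If the raw proportion of differences exceeds 0.74 in either class the
  pair is flagged saturated, Ks is reported at the cap (3.0), and the pair
  is excluded from peak detection. The Jukes–Cantor transform diverges at
  0.75; 0.74 leaves numerical headroom.

Peak detection fits a Gaussian KDE (Silverman bandwidth on values ≤ 2.0 by
default) on a 1024-point grid, takes local maxima above 5% of the peak
density, and reports both the mode location and the median of values
within one bandwidth of it — the distribution mode and the "median peak"
are both available because the two conventions differ slightly on skewed
distributions. Degenerate all-equal inputs return that value as the single
peak. Divergence ages are parameters, not constants: R = Ks/(2T) is exposed
with T an argument, since fossil calibrations are typically a bracket
rather than a point.

## Population mutation rate

θ = 4Neμ is estimated from per-site read base-count quartets. A site is
heterozygous with probability H = θ/(1+θ) (diploid, infinite sites). Per
site, given coverage n and error rate ε: a homozygous site's reads show the
true base w.p. 1−ε, else a uniform other base; a heterozygous site's reads
show either allele w.p. (1−ε)/2 + ε/6 and an off-genotype base w.p. ε/3.
The unknown genotype is marginalised uniformly within each class (4
homozygous bases, 6 allele pairs). Both classes are exchangeable in base
identity, so profiles collapse to sorted count quartets, which makes the
likelihood evaluation essentially free even at 10⁶ sites.

θ and ε are fit jointly: a log-space grid (48 × 32) followed by Nelder–Mead
refinement. The 95% CI is the θ profile likelihood (ε re-optimised at each
θ) crossing ΔlogL = 1.92, located by geometric bisection. Sites are treated
as independent (composite likelihood ignoring linkage), which is standard
for point estimation; the CI is therefore nominal under linkage, exact in
the simulator's independent-site regime. Homozygous profiles below a
minimum depth of 4 are excluded at load time. All-monomorphic input pins θ
to the lower optimisation bound with a warning.

Conversions are exact arithmetic: μ/generation = θ/(4Ne),
μ/year = μ/generation divided by the generation time. The effective
population size and generation time are inputs, never estimated. Note that
a θ of 7.12 × 10⁻³ over Ne = 112,421 gives 1.583 × 10⁻⁸ per generation at
full precision; the package reports full precision rather than a rounded
two-digit figure.

## Gene families

Expansion rules follow two deliberately different boundary conventions:
lineage-shared calls are strict (> 5 genes, > 70% from the two focal
genomes jointly, and — an interpretation made explicit here — at least one
gene from each, so a single-species family cannot satisfy a "shared"
rule); species-specific calls are non-strict (≥ 5 genes, ≥ 50% from the
focal genome). Tandem arrays are maximal runs of same-family genes whose
consecutive members are within `max_rank_gap` ranks; the default of 1
(strictly adjacent) is the conservative reading, configurable to allow
intervening genes. Expansion–tandem overlap is counted over genes, not
orthogroups. Pathway enrichment is the upper-tail hypergeometric test with
raw p against α = 0.05; Benjamini–Hochberg correction can be reported
alongside but is never silently substituted. GO-style elimination tests
are out of scope.

## The simulator

The simulator emits everything the pipeline consumes (GFF3, CDS/protein
FASTA, 12-column hit tables, profile TSVs) plus truth tables keyed by
emitted gene ids. Every gene carries a lineage path — family root → WGD
copy → species → duplication events — each step with an expected
synonymous branch length; the true pairwise dS of two copies is the sum of
branch lengths below their last shared node, and sequences are evolved
along exactly those branches. Defaults mirror the structure of a
eucalypt-style comparison: 11 chromosomes, shared WGD at dS 0.4 with 30%
copy loss (applied in the pre-speciation ancestor so both descendants share
the retained complement), speciation at dS 0.1585, heterozygosity 0.008 at
20× coverage with 1% sequencing error. Gene count per chromosome (200) and
CDS lengths (300–1,500 codons) are desk-scale choices; tests and the
acceptance script state the sizes they run at.

Codon evolution proposes single-base changes at random positions, rejects
stops, accepts synonymous changes always and nonsynonymous changes with
probability ω (default 0.2); the number of synonymous substitutions is
Poisson with mean dS × (synonymous sites), so the realised divergence hits
the target in expectation. This is a simple HKY-flavoured scheme, not a
full codon model; it is sufficient for NG86-based recovery, which is the
round trip the package needs to validate.

Rearrangements (inversions with strand flips, reciprocal translocations)
are applied to one lineage only, post-speciation, so planted blocks are
genome-specific. Tandem arrays are planted in both genomes and
species-specific expansions in the focal genome, as adjacent duplicates at
low dS — expansions are therefore tandem by construction, which is what the
overlap statistic is validated against. Hit bit scores are synthesized from
a deterministic strictly-decreasing function of true divergence (times a
length factor); randomness is confined to noise hits (uniform scores
40–80), so the score ordering of equal-length pairs is exactly the
divergence ordering. Sequence synthesis can be switched off
(`emit_sequences=False`) for synteny-only studies.

What the simulator does not emulate: repeat landscapes, intron structure,
assembly artifacts, alignment errors (hits are synthesized, not aligned),
gene conversion between paralogs, and linkage between profile sites.
Passing recovery tests therefore demonstrates the pipeline's correctness on
clean planted signal with realistic structure and noise levels, not its
robustness to annotation or alignment pathologies in real data.

## Problem sizes used in validation

Synteny recovery runs two genomes of 11 × 2,000 genes with 3 inversions,
1 translocation, and 10% noise hits; Ks-peak recovery uses 3 × 120 genes
with sequences of 300–450 codons; θ recovery uses 10⁶ sites for the point
estimate and 20 replicates of 10⁵ sites for interval coverage; the
enrichment null uses 1,000 draws of 2,000 genes from a 20,000-gene universe
against a 2,000-gene pathway (sizes at which the discrete test's exact
attainable level is within a point of 5%). These are the package's own
validation scales, chosen to exercise every code path at full signal
structure.

## Known limitations

- NG86 underestimates Ks slightly relative to ML codon models at high
  divergence; saturated pairs are excluded rather than corrected.
- The composite-likelihood CI for θ ignores linkage.
- Orthogroup inference by connected components can over-merge families
  linked by promiscuous domains; `best_score_fraction` is the only guard.
- Block extension can reshape block boundaries when added hits bridge
  formerly separate blocks; anchor sets, not block identities, are the
  stable output.
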