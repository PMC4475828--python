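# Methods

This note documents the models and procedures `ecodemarc` implements,
the defaults that matter, the synthetic data the tests rely on, and the
known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Read cleaning against an in-frame consensus

Pyrosequencing's dominant error is miscalling the length of homopolymer
runs, which frameshifts protein-coding amplicons. `readclean` aligns
each raw read globally to a fixed in-frame consensus reference with
affine gap penalties (match +2, mismatch −3, gap open −5, gap extend
−2), trying all four orientations (forward, complement, reverse,
reverse-complement; ties broken in that priority order with forward
first and reverse-complement second). Read bases that open a gap in the
reference are treated as erroneous homopolymer copies and excised, and
the read is trimmed to the reference span; a read that leaves any
reference position uncovered (a deletion relative to the frame) is
rejected ("gap"). Reads shorter than 50% of the reference or containing
non-IUPAC characters are rejected ("quality") — the quality criterion
is a documented choice, not inferred from data. A cDNA mode trims
cleaned reads to a configurable 247-column window.

Deterministic pairwise alignment against the fixed reference replaces
progressive multiple alignment: the excision rule only consumes the
read-versus-reference correspondence, and pairwise alignment makes the
operation reproducible and unit-testable against an exhaustive
enumeration oracle.

Frame-based excision presumes the read is a minor variant of the
consensus. It is valid inside roughly the ≥95%-identity envelope that
also defines lineage membership; for reads ~10% diverged from the
consensus, the optimal alignment increasingly prefers paired gaps over
runs of substitutions and legitimate variant reads get rejected. The
synthetic end-to-end runs therefore keep planted dominants within ~5%
of the cleaning reference, as a per-lineage analysis of real data
would.

*Limitation.* A read carrying both an insertion and a deletion can be
length-neutral; when the two sites are close, the optimal alignment may
prefer a run of substitutions over two gap opens, and the read then
passes cleaning with a corrupted sequence. At the default error rates
this affects a few percent of passed reads (the acceptance script
reports the measured round-trip percentage). Insertion-only corruptions
round-trip exactly; deletions are always rejected because a short read
cannot cover every reference position.

## Dereplication, HFS selection, lineage assignment

Cleaned reads all share the reference frame, so dereplication is exact
string identity with per-sample counts; variant order (descending total
count, then lexicographic) is deterministic. High-frequency sequences
(HFS) are variants with **strictly more than** a threshold of identical
reads pooled across all samples — default 50, with 10 supported as the
sensitivity setting; DNA and cDNA samples pool by default. Lineage
labels use positional identity (no realignment): A or B′ when the
respective genomic homolog is the best match at ≥95% identity; A′ when
the best match overall lies in the A′ reference set (best-match rule
with no identity floor by default, floor configurable); otherwise
unclassified.

## The Stable Ecotype Model simulator

`demarc.simulate_ses` runs a backward-in-time coalescent for *n*
sampled lineages partitioned into `npop` ecotypes (balanced round-robin
assignment; the bin statistics below depend on the number of ecotypes,
not their sizes). The clock ticks in expected substitutions per
sequence; every lineage accrues Poisson(1) mutations per tick under
infinite sites. Three event types compete:

- **Ecotype formation** (rate ω per substitution per lineage): forward
  in time a new ecotype buds off; backward, one ecotype merges into
  another (all its lineages change ecotype; no coalescence).
- **Periodic selection** (rate σ per substitution per ecotype): a
  selective sweep fixes one genotype; backward, every lineage of the
  affected ecotype coalesces into one survivor.
- **Drift** (rate per pair per substitution within an ecotype):
  ordinary pairwise coalescence.

Pairwise distances are the mutation counts along leaf-to-leaf paths
divided by the sequence length (default 324 nt), on the same scale as
Jukes–Cantor-corrected observed distances at the small divergences the
method operates on. Mutations are materialized lazily (Poisson of the
pending branch time at each merge), which keeps one simulation of ten
lineages below a millisecond. A `max_events` cap (default 10,000)
guards non-coalescing parameter combinations. With ω = σ = 0, npop = 1
and drift only, the process is the neutral Kingman coalescent; the test
suite verifies the mean bin curves against msprime.

## Bin curves and the identity ladder

A clade's diversity is summarized as the number of complete-linkage
clusters at each level of a ladder of sequence-identity criteria:
criterion *c* groups sequences whose cophenetic (complete-linkage)
distance is at most 1 − *c*. The default ladder is 1 − k·s for
k = 1..8 with spacing s = 0.005 × the sorting factor (default 1.5,
echoing the "1.5x sorting" convention), i.e. identities 0.9925 down to
0.94. The exact-identity level (criterion 1.0) is deliberately not on
the ladder: the count of strictly distinct variants is dominated by
mutation noise and carries almost no information about the ecotype
number, while crushing the match probability of every candidate model.

## Fitting: simulation-based approximate likelihood

The likelihood of a parameter point is the fraction of `n_replicates`
simulated samples whose bin curve matches the observed curve **exactly
at every ladder level** (`match_slack` is configurable but defaults to
0; slack washes out precisely the ±1-bin differences that distinguish
neighbouring npop values). The fit is two-stage:

1. **Rates.** (ω, σ) are searched on coarse log-spaced grids (ω ∈
   {0.005, 0.02, 0.1, 0.5}, σ ∈ {0.1, 0.3, 1, 3} events per
   substitution) jointly with npop ∈ 1..min(6, n); drift is *not*
   searched but moment-matched: drift = 2 / (mean pairwise distance in
   substitutions), so neutral within-ecotype diversity matches the
   observed clade and multi-ecotype models cannot shrink within-cluster
   diversity arbitrarily to overfit whatever deep coalescent split a
   finite neutral sample happens to show. The global argmax (refined
   locally by ×½/×2 steps on ω and σ) supplies the rate estimates.
2. **Ecotype number.** npop is then profiled with ω and drift held
   fixed; σ is re-optimized per candidate over the same grid (its best
   value depends on npop, since it sets within-ecotype tightness), with
   an enlarged, equal number of replicates per candidate
   (`npop_replicate_factor` × `n_replicates`, default 4 × 50). Equal
   multiplicity removes the selection bias a joint argmax suffers when
   npop = 1 spans fewer grid points than npop > 1.

Monte-Carlo likelihoods require a noise-aware argmax: the surface has a
genuine non-identifiability ridge (large ω collapses npop > 1 onto the
npop = 1 process), and higher-npop models can condition their split
depths on sample-specific clusters. The ML npop is therefore the
**smallest** candidate within min(2 Monte-Carlo standard errors, a
likelihood ratio of e) of the maximum profile value. The confidence
interval on npop is the profile-likelihood-ratio set at e⁻² — chosen
over a bootstrap for determinism and cost; both cutoffs are config
knobs. If no parameter point matches at all, the fit raises
("no fit; widen tolerance").

ω is weakly identified: once between-ecotype splits are deeper than the
loosest ladder criterion, bin counts no longer respond to split depth,
so ω estimates scatter over about an order of magnitude where σ and
npop recover well (the parameter-recovery test encodes a 3× band for σ
and a 10× band for ω).

## Demarcation

Putative ecotypes are demarcated on a midpoint-rooted neighbor-joining
tree (Saitou–Nei via scikit-bio; labels sorted before joining so
tie-breaks depend only on label order; negative branch lengths clamped
to zero; midpoint rooting chosen because the traversal needs a root and
the marker offers no outgroup). Rates are fitted **once on the full
tree**; the traversal then descends from the root, re-profiling only
npop for each clade with the global rates held fixed — conditioning
demarcation on one consistent demographic solution rather than
re-estimating rates from ever-smaller clades. A clade is accepted as a
single PE when 1 is in its npop CI (conservative mode) or when the ML
npop equals 1 (fine-scale mode); rejected clades recurse into their
children, singleton leaves are PEs, and a clade whose fit fails
entirely is split with a warning. Per-clade fits are seeded from the
clade's leaf content and shared between modes, so the fine partition
provably nests within the conservative one: ML npop = 1 implies 1 ∈ CI,
hence fine never stops higher in the tree than conservative.

## LFS assignment and abundance profiles

A low-frequency sequence joins the PE of its nearest HFS by
reference-framed Hamming distance, measured leaf-to-leaf (simpler and
directly testable against a distance oracle). "Falls within the PE's
clade" is operationalized as nearest and second-nearest HFS belonging
to the same PE; distance ties go to the PE of the globally more
abundant HFS. PE percentage per sample is (PE sequences in sample /
all sequences in sample) × 100, decomposed into dominant variant (the
PE's highest-total HFS), other HFS, and pooled LFS; replicate samples
can be summarized as mean with range. Zero-total samples yield missing
values with a warning. Absolute abundances are out of scope — only
proportions of the sequenced pool are identified.

## Ordination and statistics

**CCA** follows the ter Braak algorithm: the chi-square standardized
abundance matrix (samples as sites, variants as species) is projected
onto the row-mass-weighted span of the standardized predictors and
eigen-decomposed by SVD. Scores are reported in species-conditional
scaling ("scaling 2"), the convention fixed here because variant scores
feed the cluster test. Per-predictor explained fractions are marginal
(single-predictor constrained inertia over total). Constant predictors
raise "degenerate constraint". The implementation is cross-checked in
the tests against both a dense generalized-eigen brute force and
scikit-bio's CCA.

**Cluster permutation test.** The statistic is the mean squared
Euclidean distance of a PE's variant scores to their centroid, in the
first two constrained axes by default (configurable); the null draws
size-preserving random relabelings among all variants;
p = (1 + #{perm ≤ obs}) / (n_perm + 1). Groups with fewer than two
variants are not testable. This is the simplest faithful reading of
testing a group for nonrandom (clumped) placement in ordination space.

**G-test.** G = 2·Σ O·ln(O/E) over cells with O > 0, df = (r−1)(c−1),
p from the chi-square approximation; zero rows/columns are dropped with
a warning.

**Perturbation trends.** Distinctness: the PE × timepoint count table
is modeled with a binomial-family GLM in its multinomial log-linear
(surrogate Poisson) form — counts ~ PE + timepoint + PE × linear-time,
with per-timepoint totals conditioned out by the timepoint factor — and
heterogeneity of PE trends is the deviance difference of dropping the
interaction block against chi-square with (n_PE − 1) df. (A naive
per-PE binomial formulation double-counts each read across rows and is
anti-conservative; the calibration test would catch it.) Per-PE
direction labels come from marginal binomial GLMs of each PE's share on
time (up/down at α = 0.05, else none). An arcsine-square-root ANCOVA
variant is provided as an alternate mode; the GLM is the default
because the binomial family is the explicitly named model for the
homogeneity question. Homogeneity within a PE: binomial GLMs of each
HFS's share of the PE total, and of the LFS share, on time; flat slopes
indicate interchangeability. The reported `worst_p` is the minimum
component p — deliberately the anti-conservative summary, since the
scientific claim being protected is "no component shifted".

## Diel transcripts

Exact-match assignment counts a cDNA read toward a PE only if it equals
one of that PE's variant sequences over the shared trimmed window;
window collisions between PEs make a read ambiguous, and ambiguous
reads are discarded and tallied (determinism preferred over fractional
assignment). Short-read recruitment scans each read ungapped against
every lineage gene on both strands and recruits at best Hamming
distance ≤ 5, discarding cross-lineage ties. Normalization is
two-stage: share of the timepoint's total (assigned reads only by
default), then division by the per-category geometric mean across
non-missing timepoints, with zero counts replaced by a pseudocount
(default 0.5) *before* the geometric mean so the invariant — geometric
mean of the output equals 1 exactly — holds. Missing timepoints
(failed sequencing reactions) are carried as a mask and excluded. Note
that with relative shares, a population's share peaks where its
competitors are quietest, so only the *ordering* of diel peaks is
identified, not their absolute hours.

## Synthetic data: what it emulates and what it does not

The generator plants ecotypes as Gaussian product niches over a
temperature × depth grid (the real distributions are empirical; the
Gaussian product is a modeling choice with all parameters exposed).
Each ecotype is a dominant haplotype plus high-frequency variants at
`hfs_distance` substitutions (disjoint random sites, so HFS sit at 2 ×
`hfs_distance` from each other) and low-frequency satellites; the
70/25/5 dominant/HFS/LFS read split is configurable. Between-ecotype
separation is guaranteed by construction (exclusive mutated site blocks
sized to survive collisions) and re-checked after generation. Reads are
multinomial over (ecotype, haplotype) and corrupted by at most one
indel per homopolymer run, with per-run probability p·L^e (defaults
p_ins = 0.0015, p_del = 0.0008, e = 1, giving roughly 0.5 insertions
and 0.26 deletions per 324-nt read and cleaning pass rates in the range
deep pyrosequencing surveys report; true platform magnitudes are not
published for this setting, so these are nominal and recorded in every
run manifest). Haplotypes are substitution-only so that every indel in
a read is unambiguously a sequencing artifact — the cleaning tests have
exact ground truth.

Passing tests on these data show the chain recovers planted structure
under the model's own assumptions. They do not show robustness to what
the generator omits: chimeras, quality-score structure, PCR bias,
paired ends, recombination within the locus, non-Gaussian niches, or
biological indels.

## Problem sizes and numerical choices

The heavy acceptance properties run at sizes chosen as representative
while keeping the suite quick: ecotype-recovery and null-calibration
experiments use 50 seeded trials of 9–10 lineages on a 324-nt frame
with 50 rate-stage and 200 profile-stage replicates per parameter
point; test calibrations use 500 simulated datasets. The neutral null
is simulated with msprime (an implementation independent of the
in-package simulator) at pairwise diversity ≈ 0.5%, the within-ecotype
scale the null is meant to emulate — whole-lineage trees in this system
span only fractions of a percent substitutions per site, and within-PE
variation is a fraction of that.

*Known limitation.* At higher neutral diversity (≈1% and above), the
deep basal split of a single neutral coalescent sample increasingly
resembles a two-ecotype structure, and the ML ecotype number inflates
on a growing minority of draws; conversely, a rare neutral draw with a
genuinely three-clustered topology can let npop = 1 into the parsimony
set of a truly multi-ecotype clade. Both reflect the information limit
of cluster-count statistics at small n, not implementation defects; the
confidence-interval (conservative) demarcation is the robust mode near
this limit.

All randomness flows from explicit seeds; per-stage and per-clade seeds
are derived from content (CRC of the sorted leaf set or stage name plus
the master seed), so identical subproblems receive identical streams
regardless of traversal order, and full pipeline re-runs are
byte-identical (the manifest records checksums to prove it).
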