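# Methods

This note documents the models and procedures behind each stage, the
defaults that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## 4DTv and whole-genome-duplication dating

For a codon-aligned paralog pair, a third-codon column is a usable
fourfold-degenerate (4D) site iff both codons are gap-free and ACGT-only,
agree at positions 1–2, and that shared prefix is one of the eight
fourfold-degenerate families (GC, CG, GG, CT, CC, TC, AC, GT).  Requiring
agreement in *both* sequences is the strict interpretation; codons where
only one sequence is fourfold degenerate are excluded, since their third
position is not guaranteed synonymous in both.

The raw 4DTv is the fraction of 4D sites differing by a transversion.
Because transversions saturate, the raw fraction is corrected with the
transversion-distance component of the HKY/TN93 model family,

    d_tv = −2·πR·πY · ln(1 − Q / (2·πR·πY)),

with base frequencies pooled over both sequences at the 4D sites.  At equal
frequencies this reduces to −½·ln(1 − 2Q).  Q at or above 2·πR·πY is
flagged saturated and the pair excluded rather than clamped.  A raw Q of
exactly 0 maps to distance 0 regardless of composition, including the
degenerate case where one of πR, πY is 0.

Paranome summaries histogram corrected values with bin width 0.02 on
[0, 2] and report the modal bin's midpoint (leftmost on ties, tie flagged).
Pairs with fewer than `min_4d_sites` (default 10) usable columns are
excluded and counted: short pairs give ratios too noisy to bin.

Mode estimation from 500 pairs of ~240 4D sites is itself noisy: the
per-pair corrected value has a standard deviation near 0.09 at a true
distance of 0.5, so the modal 0.02-bin wobbles by about one bin between
seeds, and the true value can sit exactly on a bin edge.  Recovery is
therefore asserted to within one bin of the truth-containing bins, not to
exact bin membership.

## LTR insertion-age dating

The two LTRs of one element are identical at insertion; their divergence
dates it.  The p-distance excludes columns with a gap or non-ACGT character
in either sequence from numerator and denominator.  The Jukes–Cantor
correction K = −(3/4)·ln(1 − (4/3)p) is undefined at p ≥ 0.75; such
elements are flagged saturated and excluded from age profiles.  The age is
T = K / (2r) with r = 1.3×10⁻⁸ substitutions/site/year by default, the
general plant nuclear rate; the factor 2 reflects both LTRs diverging.
Ages are binned at 0.25 Mya starting at 0; the burst peak is the modal bin
midpoint.  Unaligned input pairs are globally aligned with affine gaps
(match 1, mismatch −1, open −2, extend −0.5) through Biopython's
PairwiseAligner; the aligner is pluggable, and pre-aligned pairs bypass it.

## Centromeric-satellite detection

Tandem-repeat records (Tandem Repeats Finder .dat dialect) with monomer
period within 50–500 bp are clustered by greedy single linkage: two
monomers join at ≥ 80% identity under the best circular rotation of either
monomer, on either strand, computed exactly by infix edit-distance of the
shorter monomer against a doubled copy of the longer.  Records are
canonically sorted before the greedy pass so clustering is input-order
invariant.  The base repeat is the cluster covering the most genomic bases
(tie: longer monomer).

The base monomer is mapped back by seed-and-extend: shared 12-mers
nominate candidate copy starts, nearby candidates merge, and each
candidate is verified by edit-distance alignment, kept at ≥ 80% identity
and ≥ 90% monomer coverage.  The identity+coverage rule replaces an
E-value threshold because the internal scanner does not model E-values; an
externally produced tabular hit file can be substituted.

Centromeres are called per chromosome from satellite bp summed in
non-overlapping 300-kb windows: the maximal window, merged with adjacent
windows of at least half its density, becomes the call.  When the best
window's satellite fraction is below `min_fraction` (default 0.05) the
chromosome is reported `no_call`; this operationalises "no discernible
satellite peak" for chromosomes that genuinely lack one, and the threshold
is exposed as a flag.  Monomer GC is computed over the representative
monomer only.

## Gene-family screening

A candidate passes the homology filter iff some hit has E-value ≤ 1e−5,
identity ≥ 50% and query coverage ≥ 50% (boundaries inclusive; coverage is
100·alignment_length/query_length with the candidate proteome on the query
side).  It must additionally carry every diagnostic Pfam domain of the
seed queries (superset semantics by default; exact-set mode by flag).  LEA
subfamily classification is purely domain-based — PF03760 (LEA1), PF03168
(LEA2), PF03242 (LEA3), PF02987 (LEA4), PF00477 (LEA5), PF00257
(dehydrin), PF04927 (SMP) — with a deliberately *strict* per-domain
E-value < 0.01, whereas the homology filter uses ≤; the asymmetry is kept
as the two rules are conventionally printed.  Genes supporting several
subfamilies are flagged ambiguous, not dropped.

Tandem arrays chain same-family neighbours on a chromosome when
start-to-start distance ≤ 100 kb and at most 5 non-member genes intervene;
both knobs are exposed since no universal operational definition of
"tandem array" exists.  Array span is end of last member minus start of
first.

## Expression summaries

RPKM[g,s] = counts·1e9 / (library_size·gene_length).  Library sizes
default to column sums.  The display transform is log10(RPKM+1) with
values at or below 1 RPKM floored to 0 — an RPKM of exactly 1 maps to 0,
not log10(2); the floor is a rule, not a continuity property.  Stage fold
changes average replicates on the RPKM scale, add a pseudocount (default
1 RPKM) to both stages, and rank descending; significance testing is out
of scope — fold plus rank is the nomination rule.  Row z-scores use
population sd; constant rows return zeros with a flag.  qPCR relative
expression is 2^−ΔΔCt with ΔCt = mean target Ct − mean reference Ct and
ΔΔCt relative to a calibrator sample.

## Assembly statistics

Nxx is the smallest length whose descending cumulative sum reaches x% of
the total (inclusive threshold).  Completeness percentages round half-up
to match how such ratios are conventionally printed.  GC content excludes
non-ACGT characters from the denominator.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) with no global
random state, and their outputs parse through the package's own readers.

* **Codon pairs** descend from ancestors whose codons are drawn from 4D
  families (third position at HKY stationarity), with a 20% admixture of
  non-degenerate decoy codons to exercise site classification.  Positions
  1–2 are copied unchanged; third positions evolve down two branches of
  half the requested distance under the exact HKY transition matrix
  (matrix exponential of the rate matrix normalised to one expected
  substitution per site per unit time).  Because evolution uses the exact
  P-matrix, the expected transversion fraction is computable in closed
  form and serves as an independent oracle; the inverse map from a target
  transversion distance to a total branch distance is solved numerically.
  Not emulated: selection (dN/dS), codon-usage bias, alignment error.
* **LTR cohorts** evolve a random ancestral LTR down two Jukes–Cantor
  branches of the requested age at the requested rate.  Not emulated:
  indels, gene conversion between LTRs, nested insertions — so real
  cohorts will be noisier than the simulation suggests.
* **Satellite chromosomes** plant a tandem array of independently mutated
  monomer copies (default 161 bp, 5% per-base divergence) in uniform
  random background, with low-copy decoy repeats, and emit a matching
  .dat table.  Not emulated: higher-order repeat structure, A/T-biased
  background composition, segmental duplications of the array.
* **Family fixtures** give every true member evidence passing all
  criteria and make every decoy violate exactly one (E-value, identity,
  coverage, or a missing domain), so the screen's output can be compared
  with truth exactly.  The tandem cluster places k member genes so the
  array spans the requested width exactly.
* **Expression fixtures** draw gamma-Poisson counts around lognormal
  baseline means (median ~100 counts) with dispersion 0.005, modelling
  tight pooled-material replicates; planted up-regulated genes get at
  least median baseline expression, since fold-change nomination targets
  expressed candidates and three replicates cannot recover folds of
  near-silent genes.  With these settings the planted fold is recovered
  within ~10% standard error per gene.  Not emulated: library-composition
  effects, gene–gene correlation, count outliers.

Passing recovery tests on these fixtures shows the estimators are
correctly implemented and calibrated under their own model assumptions;
it does not show robustness to the unmodelled features listed above.

## Problem sizes

The demo and acceptance runs use 400–500 codon pairs of 300 codons, 200
LTR pairs of 1 kb, one 2–10-Mb chromosome with a 300–500-copy array, a
50-gene family fixture, and 200-gene expression matrices over 40 seeds —
sizes at which every stated stochastic tolerance (3 standard errors;
mode within one bin; top-k ranking in ≥95% of seeds) is comfortably
resolvable in seconds to a few minutes on one CPU.

## Known limitations

* The 4DTv correction assumes stationary, homogeneous base composition;
  strongly shifted composition between paralogs violates the pooling.
* The monomer scanner requires at least one exact shared 12-mer per copy
  (virtually certain at ≤ 10% divergence, increasingly missed beyond).
* Tandem-array detection depends on the completeness of the gene set
  passed as `all_genes`; missing annotations undercount interveners.
* `no_call` centromere status is threshold-based, not model-based.
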