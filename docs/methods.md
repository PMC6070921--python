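# Methods

This note documents the models, parameter choices and numerical decisions
behind `arv-profiler`, and what the synthetic-data experiments do and do not
establish about real targeted-panel data.

## Panel model

The panel is a single plus-strand locus (canonical exons E1..E8, cryptic
exons CE1..CE5) plus autosomal control loci, described by one YAML document
(sequence, exon table, junction catalog, BED-style targets, RNA gene roles,
hotspot table).  Coordinates are 0-based half-open everywhere; VCF export
converts to 1-based.  Real AR is on the minus strand of X; strand is a
config attribute applied only at import/export so all junction logic runs in
transcript orientation.  The packaged fixture is a synthetic stand-in: which
cryptic exon follows which canonical exon differs between published AR-V
catalogs, so the exon composition of each named variant is configuration
data, not code.  The fixture uses AR-V7 = E3→CE3, AR-V9 = E3→CE5,
AR-V3 = E2→CE4, plus minor variants V4/V5/V6; only the junction *catalog*
matters to the algorithms.  All cryptic exons sit in the intron between E3
and E4 so that every junction, including E2→CE4, runs left to right.

## Junction quantification

Signatures are 130 bp + 130 bp concatenations (truncated at short exons);
signature strings must be pairwise distinct or configuration fails early.
Assignment is exhaustive ungapped matching rather than an external aligner:
deterministic, exactly reproducible, and oracle-checkable.  Defaults:
`min_overhang` 10 bp on each side of the boundary, `max_mismatches` 3
(~2% of a 150 bp read).  A read is assigned only when a unique signature
achieves the minimal mismatch count among all valid placements of the read
and its reverse complement; ties across signatures are discarded as
ambiguous, never fractionally allocated.  The production matcher uses an
exact-window dictionary fast path with a full-scan fallback; tests assert
read-for-read agreement with an independent brute-force Hamming scan.

Fractions follow the upstream-exon-group formula literally over the
catalogued junctions (whether reads anchored at the upstream exon but
matching no catalogued junction should enter the denominator is ambiguous;
they do not).  The confidence bound is the lower endpoint of the exact
Clopper–Pearson two-sided 95% interval — chosen because it is valid at the
small counts typical of low-fraction variants and exactly reproducible; the
binomial model itself is an assumption, not a derivation.  Full-length AR
expression is measured as the count of the canonical junction sharing the
variant group's upstream exon (E3→E4 by default).

## Copy number

Read starts are counted in 400 bp windows stepped every 200 bp (50% overlap;
the step is a choice — only "overlapping" is inherent to the window design)
and fully contained in each target.  Normalisation is within-sample: AR
window counts are divided by the median control-gene window count, and the
median of those ratios, times the configured control ploidy (2), is the
estimate.  This removes library-depth effects without a reference cohort;
per-sample total-count scaling cancels in the ratio.  With AR X-linked and
one copy in an unaltered male sample, the estimate is calibrated so such a
sample reports 1.0, making the gain rule (> 1 copy) meaningful.  Labels are
a pure function of the estimate (gain iff 1 < cn ≤ 2, amplification iff
cn > 2); for a sample whose true copy number sits exactly on a threshold the
label is decided by sampling noise in the estimate, which is inherent to
any strict threshold rule.  No segmentation and no tumour-purity correction
are attempted.

## Rearrangements

The split-read caller is specified from scratch (the published description
of such pipelines is a sketch): because the panel reference is only
kilobases, the search is exhaustive rather than seeded — for a read that
fails contiguous mapping (within twice the per-segment budget), mismatch
prefix-sums of the read and its reverse complement against every reference
diagonal are evaluated, and every prefix/suffix split with both segments
≥ 25 bp and ≤ 2 mismatches each is considered, with the additional
requirement that the 4 bases adjacent to the split match exactly on both
segments — without this clean-anchor rule the mismatch budget can carry a
segment across the true junction, widening the effective junction-read
window and biasing support and VAF upward by ~10–15% relative (measured on
simulated deletions).  Among valid splits the one
with the fewest total mismatches wins; ties (micro-homology at the junction)
are broken by the orientation-canonical breakend tuple, so both sequencing
orientations of the same junction report the same, leftmost-in-genome
breakpoint.  Truth comparisons still allow a tolerance of the homology
length.  Events merge split alignments agreeing in orientation and within
10 bp on both breakpoints (median breakpoint reported); the support cut-off
is 10 split reads.  VAF = split support / (split support + reads mapping
contiguously across breakpoint A with ≥ 25 bp on both sides); reads from
the rearranged allele that do not cross the junction map contiguously and
are counted in the denominator, which biases VAF slightly downward exactly
as read-based VAFs do in practice.  Discordant mate spacing is not used as
calling evidence — the cut-off is defined in split reads — and mates are
mapped independently.

## Variant calling

A substitution-only pileup caller: per-position allele counts over targets
from contiguously mapped reads, a call where the top non-reference allele
has depth ≥ 50, VAF ≥ 5% and ≥ 5 alt reads.  These thresholds are this
package's defaults (exposed as flags): with a 0.2% substitution error rate,
errors reach neither the 5% VAF nor the 5-read floor at panel depths, which
the specificity tests confirm.  Hotspot names (L702H, H875Y, T878A analogs)
attach by (position, alt) lookup; amino-acid naming is configuration, not
codon translation.  No indels, no strand-bias or quality modelling.

## Expression score

Counts are divided by the geometric mean of the three housekeeping genes
with a 0.5 pseudocount — robust to single dropouts and standard for
reference-gene scaling; the pseudocount breaks exact scale invariance by
< 0.1% at realistic counts, which the tests bound explicitly.  Z-scores use
the cohort mean and standard deviation (ddof 1, ≥ 3 samples required;
zero-variance genes contribute 0) and the signalling score is their sum over
the five androgen-responsive genes.  The AR-V level rule assigns the exact
5% boundary to "low" (both published inequalities are strict; a
deterministic rule is required).

## Cohort statistics

Mann–Whitney U is exact (full enumeration, via scipy) for pooled n ≤ 20
without ties, otherwise the normal approximation with tie and continuity
corrections — the switch point is a tractability choice.  Spearman p-values
use the asymptotic t approximation with n−2 degrees of freedom.  Raw
p-values are reported (mirroring a three-comparison design); Holm adjustment
is available behind a flag.  Missing assay fields are excluded
pairwise-complete with exclusion counts logged, never imputed.

## Synthetic data: what it emulates, and what it does not

RNA reads are 150 bp single-end drawn uniformly from spliced isoform
sequences with independent substitution errors (default 0.2%); the
single-end choice simplifies assignment bookkeeping relative to the
paired-end assay it emulates and is a recorded deviation.  The requested
per-variant fractions are *junction-group* fractions, so the generator
solves for the underlying isoform mixture in closed form by a backward pass
over the junction groups (a variant branching late also feeds every earlier
group's denominator).  `depth` is the expected number of reads overlapping
a junction by at least one base.

DNA fragments are truncated-normal (mean 180 bp, sd 30 bp, matching a
150–200 bp library), paired 150 bp forward–reverse, with per-locus fragment
counts proportional to copy number (`depth` = read-base coverage of a
two-copy region).  For each engineered rearrangement, fragments overlapping
breakpoint A derive from the rearranged allele with probability VAF;
hotspot alternate alleles are emitted per fragment at their VAF.  One master
seed drives everything; per-sample seeds are derived by stable hashing of
(master seed, sample id), so cohorts are byte-reproducible.

Not modelled: PCR duplicates, GC and capture-efficiency bias (coverage is
uniform within targets — no per-bait efficiency data exist to emulate),
indels, quality-score structure, RNA degradation.  Passing tests therefore
demonstrate the *algorithms* are correct under the stated error model and
recover known truth at realistic depths; they do not certify performance
under capture non-uniformity or alignment artefacts of genome-scale data.

Default cohort designs: a three-group study (prostatectomy n=24, lymph-node
metastasis n=8, metastatic CRPC n=30) with CRPC-only copy-number gains and
amplifications (up to 68 copies), occasional rearrangements at VAF
2.6–10.9%, hotspot mutations in ~20% of CRPC samples, and AR-V fractions up
to 13% (V7) / 7% (V3, V9) coupled to elevated AR expression; and a
two-group CRPC-vs-naive contrast used for the power analyses.  Where a
published value existed (coverage ranges, VAF range, maximum fractions,
copy-number extremes, group sizes) it set the defaults; remaining values
(expression means, dispersion 0.15, coupling noise 0.15) are one-time
choices of plausible magnitudes.

## Problem sizes used in the shipped checks

Oracle equivalence runs 20 samples at junction depth 2000; fraction
calibration 200 samples at denominators ≈ 1100; copy-number recovery at
read depth 300; rearrangement detection at depth 2000 with a 50-sample
clean control at depth 500; the cohort contrast 20 seeds of 15 + 15 samples
at depth 250.  The acceptance script uses the same designs at moderately
smaller replicate counts.
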