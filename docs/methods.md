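# Methods

This note records the models, conventions, and numerical choices behind
svdivkit, in the spirit of a statistical-software methods appendix.

## Coordinates and SV representation

All internal coordinates are 0-based half-open (BED-compatible
arithmetic); VCF's 1-based inclusive coordinates are converted exactly at
the I/O boundary, so the mapping is a bijection. An insertion is stored as
a breakpoint (`end == start`) with its size in `length`; for every other
class `length == end − start`. Footprint statistics (total affected bp)
count an insertion as `length` bases so that inserted sequence contributes
to genome-coverage figures. Strand is ignored throughout: all SV
set-arithmetic here is strand-agnostic.

Records outside the 50 bp – 2 Mb size window are retained and flagged
`out_of_range` rather than dropped; divergence ranking skips flagged
records by default. CPX ("complex") is an opaque class: it is summarised
and matched (CPX↔CPX, by the deletion rule) but never interpreted.

When writing VCF, SVLEN is emitted only for insertions: recent htslib
versions force-derive END from SVLEN for symbolic alleles (VCF 4.4
semantics), which would clash with the END convention used here; for
non-INS records the length is always recoverable as END − POS + 1.

## Call-set matching

Two DEL/DUP/INV/CPX records match when each covers ≥ 50% of the other
(reciprocal overlap on genomic footprint — the phrase "50% reciprocal
similarity" has no other standard reading, and DEL/DUP are never
cross-matched). Insertions are points, so the reciprocal rule is undefined
for them; they match by breakpoint distance ≤ 1 kb and length ratio ≥ 0.5
(both configurable). Matching between two call sets is greedy 1-to-1 in
decreasing order of the pair score min(frac_a, frac_b), with deterministic
symmetric tie-breaking (smaller start, then record ids). Greedy rather
than bipartite-optimal matching is the standard choice in SV merging;
differences arise only in pathological overlap configurations. Because
thresholding only truncates the greedy acceptance order, the matched-pair
set at a higher threshold is always a subset of the set at a lower one.
The sweep-line implementation is validated against an all-pairs
brute-force oracle on 500-record random fixtures.

A target record is assembly-specific when it matches nothing in any other
call set; the intersection is computed independently per pair of call
sets, and SV-class agreement is required when matching.

## V_ST and the clamp

V_ST = (V_T − V_S)/V_T with population variances (denominator n) and
sample-size weights; V_T = 0 yields 0. With these conventions the pooled
variance decomposes exactly into within + between, so the raw estimate is
already non-negative; the clamp to [0, 1] documented in the API is a
defensive guarantee, and the raw value is retained alongside. mV_ST is the
identical computation applied to insertion dosage (0/1/2) genotypes.
`hwe_expected_vst` evaluates the statistic on HWE moment expectations
(mean 2p, variance 2p(1−p)) without sampling; at the study frequencies
0.544/0.317 and sample sizes 38/39 it gives ≈ 0.0999, close to — but not
required to equal — the genotype-based published value 0.106.

Candidate ranking first removes loci with repeat content ≥ 70% (short-read
genotyping is unreliable inside repeats), then flags loci at or above the
empirical (1 − q) quantile with linear interpolation between order
statistics, so "top 5%" is exactly reproducible.

## Drift null

Each replicate draws an ancestral frequency p₀ (a fixed value, a uniform
range, a weighted frequency spectrum, or a user callable), evolves the two
descendant populations independently for T generations of binomial
Wright–Fisher sampling of 2N gametes, then draws the study-sized diploid
samples as Binomial(2, p) dosages and recomputes the statistic (V_ST or
allelic divergence). The empirical p-value uses the +1 correction,
(1 + #{null ≥ obs})/(1 + reps), so it is never zero. Replicates where the
statistic is undefined (allele fixed or lost everywhere → zero pooled
variance) score 0 and are reported in a degenerate-replicate count, not
raised as errors.

Defaults — N₁ = N₂ = 10 000, T = 1200 generations, p₀ = pooled observed
frequency — are placeholders for an unspecified single-split demography
and are recorded in the result metadata; every parameter is exposed on the
CLI. No recombination, migration, or multi-epoch demography is modelled:
the null is deliberately minimal.

Calibration: by construction the type-I error of the observed statistic at
the simulated 95% cutoff is 5%; the acceptance suite verifies 5% ± 1% with
a 10 000-replicate cutoff and 2 000 fresh replicates (Monte-Carlo SE
≈ 0.5%).

## EHH and association

EHH uses the pairwise-homozygosity definition: among the c carriers of the
focal allele, EHH(x) = Σ_h C(e_h, 2)/C(c, 2) over the distinct haplotype
stretches from the core to x inclusive. Extending the stretch refines the
partition, so the curve is exactly 1 at the core and non-increasing
outward — both are asserted as invariants, not tolerances.

Association is ordinary least squares of the trait on allele dosage plus
optional caller-supplied covariates, with listwise deletion of missing
values, a two-sided t-test on the dosage coefficient, and the sign
reported separately. A plain linear model (not a mixed model) is used
because the intended setting pools samples from populations with no
detected genetic substructure; a population covariate can be supplied
where that assumption fails. The joint two-locus model regresses on the
single combined score dosage_A + dosage_B, testing whether two SVs act
additively in the same direction. BH FDR is the step-up rule (own
five-line implementation, cross-checked in the tests against both a
brute-force definition and statsmodels), applied per trait or across the
flattened traits × loci grid ("the most rigorous adjustment").

## Enrichment

The permutation scheme re-places every SV uniformly at random on its own
chromosome, preserving its length (the regioneR-style convention, recorded
in the output metadata); overlap is counted per SV (≥ 1 bp with ≥ 1
element), and insertions count through a 1-bp breakpoint interval, since a
zero-length interval can never overlap anything. The empirical p-value is
tie-inclusive with the +1 correction, which makes it conservative at the
atoms of the discrete overlap-count distribution — the calibration test
therefore checks validity (P(p ≤ t) ≤ t) plus approximate uniformity
rather than exact uniformity. The gene-set overlap test reports the odds
ratio ad/bc with the Haldane 0.5 correction applied to all cells iff any
cell is zero, and a Pearson chi-squared p-value without continuity
correction; the gene universe must be supplied by the caller, since no
default universe is defensible.

SV-to-gene assignment uses a strict < 5 kb distance (overlap = distance
0): a gap of exactly 5 000 bp does not qualify.

## Assembly evaluation

Nx is the smallest length L such that sequences ≥ L cover x% of the
assembly. A reported scaffold gap is a maximal N run of at least 10 bases
(shorter runs are treated as local ambiguity, distinguishing ambiguity
codes from true scaffold gaps); contigs, however, are split at *every* N
run, so the sum of contig lengths equals the non-N base count exactly —
the two thresholds serve different purposes and the convention keeps the
conservation identity exact. Non-nucleotide characters are counted as N
with a warning.

A reference N-gap counts as closed only when a *single* alignment block
spans it with ≥ 50 anchored bases on each flank (configurable); two
adjacent blocks each covering one flank do not close a gap, because
nothing ties their intervening assembly sequence together. An NRS is
archaic-shared when ≥ 80% of its bases have archaic-read depth ≥ 1 (both
thresholds exposed); it sits at a clean insertion point when its two
flanks anchor to the same reference chromosome, same orientation, with
|reference gap| ≤ 100 bp — the absolute value tolerates small flank
overlaps from breakpoint micro-homology. An unaligned flank makes the
insertion-model call indeterminate (None), never negative.
Assembly-specific NRS events are those matching nothing in other genomes'
event sets under the insertion matching rule.

## Synthetic data: what it does and does not emulate

The generators encode the study conditions as defaults: two populations of
38 and 39 diploid samples; one planted deletion locus at frequencies
0.544/0.317 and one insertion locus at 0.240/0.130 among null loci with
equal frequencies drawn once from U(0.05, 0.95); 19 clinical-scale traits
with a −3-per-allele effect of the deletion on pulmonary arterial pressure
and a +2 effect of the insertion on the FEV1/FVC ratio, plus Gaussian
residuals at clinically realistic SDs. Genotypes are independent
Binomial(2, p) draws — HWE holds exactly and there is no linkage
disequilibrium, relatedness, genotyping error, or missingness unless
planted. Haplotype panels are independent sites except for the sweep
construction (carriers copy a founder haplotype over the sweep span with
2% per-site mutation). Call sets place events on a coarse grid so distinct
events can never cross-match, with breakpoint jitter small relative to
event size. The toy assembly has uniform base composition and clean block
alignments.

Consequently, passing tests demonstrate the *correctness and calibration
of the statistical machinery under its own assumptions* — they do not
demonstrate robustness to LD, population structure, repeat-driven
genotyping error, or alignment ambiguity in real data, all of which the
generators deliberately omit.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is reproducible
bit-for-bit. The test-suite and acceptance problem sizes — 500-record
call-set fixtures, 10 000/2 000-replicate drift calibrations, 1 000
permutation replicates for p-value uniformity, cohorts of 868 + 94 for
parameter recovery — were chosen so each check has clear statistical
resolution (tolerances of 2 SE or 3 Monte-Carlo SE) while the whole chain
runs in seconds on one CPU.

## Known limitations

- The drift null's default demography is a placeholder; conclusions about
  selection at a real locus require externally justified N, T, and p₀.
- V_ST has no finite-sample bias correction; at n ≈ 40 per population the
  null distribution is wide, which is exactly why the drift null rather
  than a fixed V_ST threshold should judge significance.
- The insertion matching rule (window + length ratio) ignores inserted
  sequence content; sequence-level comparison is out of scope.
- The permutation scheme preserves chromosome and length but not local
  context (GC, repeat density); fold estimates inherit that simplification.
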