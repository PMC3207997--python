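# Methods

## The quantification model

Repeat families, not loci, are the unit of measurement. The reference is a
*repeat database*: one entry per annotated repeat instance, extracted from the
genome in forward orientation with a `flank_bp = 50` flank of genomic context
clipped at chromosome bounds. Overlapping annotations (or overlapping flanks)
yield duplicated sequence by design — the database is a read-capture space,
not a partition of the genome. Reads aligning anywhere in an entry, including
only within a flank, count toward that entry's family: the flanks exist
precisely to capture junction-spanning reads, and no rule excludes them.

Because the database is internally repetitive, a read that aligns at all
usually aligns to many entries of its family. Exactly one best alignment is
kept per read, so per-family counts accumulate as if along a consensus
element. The price is locus-level information: nothing in this package can
say *which* genomic copy was transcribed.

### Alignment policy

The aligner is a seed-and-extend implementation of the stated quantification
constraints rather than a general-purpose mapper:

- reads are trimmed 3'-ward to `read_len = 76`;
- a candidate placement requires an exact match of the read's first
  `seed_len = 20` bases (on the minus strand, of the corresponding tail of
  the reverse-complemented read) — N never matches anything, including N;
- extension is ungapped Hamming comparison of the remaining bases;
  placements with more than `max_mismatches = 3` mismatches are discarded
  (the seed is exact, so the cap effectively applies outside the seed);
- among survivors the minimum-mismatch placement wins; ties break by lowest
  (entry id, + before −, offset), with entry ids assigned in database
  construction order. This makes runs bit-reproducible and family assignment
  stable.

The published constraint fixes only the exact seed and "best alignment"; the
mismatch cap and the tie-break are configuration here. Quality scores are
ignored (the policy is purely sequence-based), and indels are out of scope
for quantification — the L1 module uses a gapped aligner instead. A separate
genome-unique mode retains only reads with exactly one surviving placement
genome-wide, for repeat-masked intronic/intergenic compartment counting.

`ExhaustiveScanner` is a second, independent implementation of the same
model: a full Hamming scan of every offset, entry and strand with no seed
hashing. It is quadratic and exists to validate the seeded path; the
acceptance suite checks 100% agreement of per-read best mismatch counts on a
five-thousand-read batch.

### The uniform-transcription null

The null hypothesis — repeat-derived reads arise uniformly over repeat
sequence space — is simulated, not computed analytically: `n_datasets`
independent sets of `read_len` reads are extracted verbatim (no sequencing
error) at start positions uniform over all valid (entry, offset) pairs, with
uniform strand, and pushed through the same aligner and counter as observed
reads. Entry selection is therefore weighted by `entry_len − read_len + 1`
valid starts, not by entry count, and entries shorter than the read length
contribute nothing. Simulating rather than using the analytic start-share
vector is the point: cross-family misassignment and any other alignment bias
affect both conditions identically and cancel in the comparison. A
coding-space variant draws reads from a CCDS-like database and aligns them
against the repeat database, to ask how much apparent repeat expression
uniform coding transcription could produce.

Defaults: `n_datasets = 100` (the published design), `reads_per_dataset =
50,000` as a desk-scale default (the published runs used ~400,000
repeat-derived reads per dataset and 7,881,000 for the coding space; both are
plain configuration). Datasets use child seeds spawned from one seed, so they
are independent yet reproducible.

### The negative-binomial exact test

Observed libraries (technical replicates — mates and lanes — aligned
separately, then pooled per biological sample by elementwise count sum) and
simulated datasets form the two conditions of a count comparison, run per
family:

- **Size factors**: `s_j = median_f ( k_fj / geomean_j(k_f·) )`, families
  with any zero excluded from the median; estimated jointly across both
  conditions by default (configurable per condition — the original
  description leaves this open).
- **Dispersion**: per family, base mean `q_f = mean_j(k_fj/s_j)` and raw
  (extra-Poisson) variance `v_f = max(var_j(k_fj/s_j) − q_f·mean(1/s_j), 0)`.
  With only a dozen families the original method's local regression of
  variance on mean is unstable, so pooling across families uses isotonic
  regression of `v` on `q`, interpolated at the tested mean; per-family
  method-of-moments is available as an alternative. Flooring at zero means
  total variance never falls below shot noise.
- **Exact test**: with `S = k_A + k_B` and pooled per-unit mean
  `q₀ = S / (Σs_A + Σs_B)`, condition sums are modeled as
  `K_A ~ NB(μ_A, σ²_A)` with `μ_A = q₀ Σ_j s_j` and
  `σ²_A = μ_A + v_A(q₀) Σ_j s_j²` (NB parameterized by mean/variance;
  Poisson when the raw variance is zero). The p-value is
  `p = Σ_{a+b=S, P(a)P(b) ≤ P(k_A)P(k_B)} P(a)P(b) / Σ_{a+b=S} P(a)P(b)`.
  All masses are log-space; the enumeration is exact up to `S = 2·10⁶` and
  windowed to a ±12σ region around the mode and the observed split beyond
  that (excluded tail mass < 1e-12). `S = 0` returns p = 1 by convention.
  Alongside the linear-scale p-value a log10 p-value is carried through,
  including a log-space BH track, so results stay informative after linear
  underflow.
- **Fold change** is oriented simulated/observed: an overexpressed family
  (more observed reads than the null predicts) has fold change < 1. This
  orientation is forced by consistency between the published table's stated
  directions (Alu overexpressed at 0.82, L1 underexpressed at 2.14).
- **Multiple testing**: Benjamini–Hochberg step-up across families
  (statsmodels' `fdr_bh` behind the `bh_adjust` surface).

Calibration, measured by the acceptance suite under the synthetic study
conditions: type-I error ≤ 0.08 at nominal 0.05 over ~1,000 same-law NB
simulations (α = 0.1, 10 vs 100 samples), and ≥ 90% of twenty multiplier-1
end-to-end replicates yield no BH-adjusted rejection.

### L1 5' start profiling

Reads whose best repeat-database hit is family L1 are realigned with a local
Smith–Waterman aligner (match +1, mismatch −1, gap open −2, gap extend −1,
`min_score = 50` on 76 bp reads; the original analysis names a chained
aligner but no parameters) against a panel of full-length L1 consensus
sequences, both strands, one best hit per consensus with ties broken toward
the smallest start. Each read's 1-based start coordinate is averaged over its
per-consensus hits and histogrammed (default bin 100 bp) for observed reads
and for a draw of the simulated null. Gapped alignment is appropriate here
because reads are compared against *consensus* sequences they diverge from,
not against their own genomic copies. Biopython's `PairwiseAligner` provides
the dynamic program; the test suite checks its scores against an independent
quadratic Gotoh implementation.

## The synthetic data generator

`make_genome` plants truth-tracked repeat copies into i.i.d. uniform
background: per family, a random consensus of configurable length; copies
drawn until the family's bp share of the target repeat fraction (default
0.45 of the genome, matching the repeat content the analysis assumes) is
met, each copy substituted at the family divergence rate, 5'-truncated
(geometric retained 3' length) unless full length, reverse-complemented on
the minus strand. Placement is block-based and non-overlapping with a
minimum 110 bp gap — deliberately larger than twice the 50 bp flank so
flanked database entries never overlap and the database's valid-start space
equals the genomic one. Genes are placement blocks too: background intervals
of `gene_len`, a configurable fraction of which enclose one small repeat
copy ("embedded"), so gene placement always succeeds and never collides with
other copies. The default mix has 12 families with an Alu-like
short/abundant family, a 3 kb L1-like family with 10% full-length copies
(a desk-scale stand-in for the ~6 kb element), and satellites/DNA
transposons at smaller shares.

`make_reads` draws each read from a mixture: uniform background over the
genome, gene transcripts with log-normal per-gene levels (fixed by the
expression seed so replicate samples share them), and repeat transcription
with family weight ∝ multiplier × flanked start-share. With all multipliers
at 1 the repeat component draws starts uniformly over the *flank-extended*
repeat intervals — exactly the null simulator's valid-start space — so
multiplier-1 data is generated under the uniform-transcription null and the
calibration tests are honest type-I measurements. The calibration scenarios
also use genes without embedded copies: an embedded repeat inside a highly
expressed gene is a genuine violation of uniformity (the effect the
coding-space simulation exists to probe), not an error of the test.
Mate pairs are two independent draws from the same law, matching their
downstream treatment as technical replicates; fragment-size structure is not
modeled. Substitution errors are applied per base (default 0.005); indels,
quality profiles, GC bias and CpG-elevated divergence are not simulated, so
passing tests demonstrate correctness of the inference machinery under the
stated model, not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Desk-scale defaults keep every stage interactive: 250 kb genomes
(~137 kb repeat database), 2,000-read samples, 20-dataset nulls in tests;
the acceptance script's largest single computation is a 100,000-read
uniformity check. Published-scale numbers (100 datasets, 4·10⁵–7.9·10⁶
reads) remain plain configuration. Other numerical choices: NB masses via
`scipy.stats.nbinom.logpmf` with a Poisson fallback when variance ≤ mean;
tail-sum tie tolerance 1e-8 relative in log space; reported p-values print
as 0 only on linear underflow, with the log10 column retaining the value;
coordinates are 0-based half-open internally and 1-based inclusive in
reports.

## Known limitations

- One-hit-per-read accounting cannot attribute expression to loci, and
  family counts inherit any systematic misassignment between similar
  families (the simulation controls for it in the *test*, but the counts
  themselves remain confounded).
- The BH step-up applied to the published table's 3-significant-figure raw
  p-values reproduces the printed adjusted values except one family whose
  printed adjustment differs in the third digit (4.23 vs 4.24 ×10⁻⁹²),
  consistent with rounding of the printed input.
- The isotonic dispersion pooling is monotone by construction; if true raw
  variance were non-monotone in the mean across families it would bias
  variance estimates (with 12 families there is no power to detect this).
- The uniform null draws whole reads within entries; reads spanning entry
  ends are not simulated, so entries shorter than the read length are
  invisible to the null.
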