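# Methods

## The assay being modelled

FLT3 internal tandem duplications (ITDs) are in-frame insertions in exons
14–15 that duplicate an adjacent reference segment, and their burden after
therapy (measurable residual disease, MRD) is prognostic in AML.  The
package models a single-amplicon deep-sequencing assay: a 208 bp PCR
product over FLT3 exons 14–15 (hg19 chr13:28,608,108–28,608,315, primer
pairs forward chr13:28,608,315–28,608,296 and reverse
chr13:28,608,129–28,608,108), sequenced as 150 bp paired reads — 300 bp
reads for long duplications — at depths in the 10^5–10^6 read range.

The core idea is the tracer *seed*: once an ITD is discovered and
decomposed, a 12–20 bp window of the mutant molecule that spans the ITD
junction and occurs nowhere in the wild-type amplicon (either strand) is
designated.  MRD in any later sample is then the fraction of reads
containing that seed as an exact substring, which is cheap, highly
specific, and insensitive to how an aligner represents the insertion.

## ITD structure and canonical records

An ITD insert decomposes as a *spacer* (novel bases) plus a *duplication*
(an exact copy of adjacent reference).  Reading the insert at the 3' end
of its origin, the duplication is the longest insert suffix matching the
reference ending at the insertion anchor.  Because the last inserted base
then necessarily equals the reference base at the anchor, every such
event can be shifted left base-by-base (rotating the insert) without
changing the mutant molecule — the familiar indel left-alignment
ambiguity.  Records are therefore canonicalized at the leftmost
placement, where the same event reads *duplication + spacer* with the
duplication copying the reference immediately 3' of the anchor; the
mutant molecule then reads duplication-copy, spacer, origin.  The
duplication and spacer strings are identical in both presentations (this
is checked by tests on worked examples), so canonicalization changes the
bookkeeping, not the biology.  All equivalent placements of one clone
map to one canonical record; this is property-tested by exhaustively
enumerating placements on small references.

A minimum duplication of 6 bases (evaluated at the canonical placement)
separates ITDs from plain insertions: shorter matches are too likely to
be coincidental homology.  Frame preservation (length divisible by 3) is
reported as a flag, never enforced, so out-of-frame artifacts remain
visible.

## Alignment and junction evidence

Reads are aligned to the amplicon with an affine-gap dynamic program
(match +1, mismatch −2, gap open −4, gap extend −1, a gap of length L
costing 4 + (L−1)); alignments may start and end at any cell, with the
unaligned read prefix/suffix reported as soft clips.  Free clips at
arbitrary reference coordinates are essential for amplicon ITD data: a
mate that begins inside the insert must clip mid-reference, and a long
insert is cheaper to clip than to open as a gap whenever the flank beyond
it is shorter than the gap cost.  A plain-Python brute-force DP with the
same scoring serves as the oracle in tests; scores must agree exactly.

Production alignment short-circuits: reads that are exact substrings of
the amplicon (either strand) are trivially placed; edlib's edit-distance
alignment screens the rest, and only reads whose unit-cost alignment
contains indels (or is high-distance) reach the full DP.  Identical read
strings — the overwhelming majority at realistic error rates, since all
error-free reads of one template are the same string — are memoized.

Junction candidates come from two evidence classes:

* **Internal insertions** — an `I` operation directly yields the inserted
  bases and the anchor.
* **Soft clips** (≥ 12 bases, the minimum seed size; shorter clips cannot
  anchor a unique junction).  A clip is remapped onto the reference: the
  longest clip suffix (for trailing clips; prefix for leading) that
  occurs in the reference at a position compatible with a duplication
  pins down where the molecule resumes reference sequence, and the
  complete insert is reconstructed as novel-remainder + skipped
  reference.  This one rule covers reads that run past the insert into
  flanking reference, reads that start inside the insert, and the
  tandem-specific "overrun" where the aligner matches straight through
  the first copy of the duplication and clips the rest.  Each
  reconstruction is validated by requiring the clip plus 12 adjacent
  matched bases to be a substring of the implied mutant molecule;
  validation failures (junction mis-placements, errors near the
  junction) fall back to the raw clipped bases, flagged incomplete.
  Boundary shifts of up to 6 bases are retried because coincidental
  matches can drag the aligner's match run across the true junction.

Candidates are clustered by exact (inserted sequence, anchor) identity —
no error-tolerant merging, mirroring the identical-sequences counting
rule — after which incomplete clip strings that are a proper prefix or
suffix of a longer complete candidate at the same anchor fold into it
(evidence class `mixed`), since reads ending inside the insert truncate
it.  A group is called a true ITD when it has at least 4 supporting
reads (the strict "more than 3" rule) in a sample of at least 10,001
reads (strict "more than 10,000").  Both thresholds are configurable.
The depth denominator is total primary reads over the amplicon, which
for a single-amplicon assay coincides with sample depth.  Secondary and
supplementary alignment records are excluded everywhere: one vote per
read.

## Seed design

Candidate seeds are all windows of the reconstructed mutant, 12–20 bp
long, that overlap the insert-start or insert-end junction with at least
4 bases on each side — so no single terminal mismatch can convert a
wild-type read into a seed match — and that never occur in the wild-type
amplicon or its reverse complement.  For a pure tandem duplication the
only novel context is the copy-end→copy-start join; enumerating both
boundaries plus the uniqueness screen handles this without a special
case.  Among qualifying windows the selection is deterministic: shortest
first (every extra base is another chance for a sequencing error to
erase a real seed read), then most centred on its junction, then
lexicographically smallest.  Uniqueness is screened against the amplicon
only, matching the assay's single-locus read space; a genome-wide screen
would be a trivial extension but is not what the counting denominator
sees.

## MRD quantification

A read counts as a seed read when it contains the seed exactly on either
strand; each read counts once, mates count independently, and no PCR
deduplication is attempted (amplicon reads are indistinguishable by
position, so deduplication is impossible in principle).  VAF = seed
reads / total reads.  Multiple ITDs in one sample sum (capped at 1);
repeat tests at one timepoint take the maximum VAF.  Cut-off calls are
strictly greater-than, at a default ladder of 2% (the fragment-analysis
limit), 0.1%, 0.01% and 0.001%.  A clone is "detected" at the same ≥ 4
seed-read floor used in discovery, keeping discovery and tracing
consistent.

Exact matching makes the measured VAF a slight underestimate: a seed of
length L at per-base error rate ε loses reads at rate 1 − (1−ε)^L, so
the expectation is p·(1−ε)^L (≈ 1–2% relative at ε = 0.001, L = 12–19).
This is asserted as a property and is the simulator's analogue of the
bench observation that exact tracing underestimates high-burden samples
relative to sizing assays.

## Probit limit of detection

Detection probability across a dilution series is modelled as
Φ(a + b·log10 VAF) and fitted by maximum-likelihood probit regression
(statsmodels GLM); the LOD is the VAF where the fitted curve reaches
95%, with a delta-method 95% interval on the log10 scale,
back-transformed.  Zero-VAF blanks never enter the regression (log10
undefined); they only corroborate negativity.  Perfectly separated
tables cannot be fitted: the LOD is then reported as the log-scale
midpoint between the highest all-miss and lowest all-hit levels with
that bracket as the interval and a separation flag set.  Recovery of a
known curve (LOD 6×10⁻⁵) from 50 Bernoulli replicates at each of six
levels is required to land within ±30%.

## The simulator

The simulator is the stand-in for the bench dilution experiments:
wild-type and mutant template molecules mixed at specified molecular
VAFs, fragments equal to the whole amplicon (amplicon libraries have no
size selection), paired mates reading inward from the fragment ends,
and i.i.d. per-base substitution errors (uniform among the three
alternatives).  Since every fragment of one template is identical,
error-free reads share a single string object and only error-carrying
reads are materialized — 10⁶-read samples simulate in seconds.  A single
integer seed drives everything; dilution-series sub-streams derive from
stable (seed, level index, replicate) spawn keys, so adding levels or
replicates never perturbs earlier samples, and identical seeds give
byte-identical FASTQ.

What the simulator deliberately does not model: indel sequencing errors
(seed matching is exact and clustering is exact-identity, so indel
errors only reduce counts — which the underestimation property already
bounds), platform-specific error profiles, quality-score variation, PCR
bias and chimeras, and fragment-length variation.  Passing tests
therefore demonstrate the algorithmic pipeline (junction recovery,
canonicalization, seed uniqueness, counting statistics) under clean
Illumina-like substitution noise, not robustness to every artefact of
real libraries.  The packaged 208 bp reference sequence is a synthetic
stand-in with realistic composition and unique 10-mers on both strands;
any user-supplied 208 bp FASTA drops in, since no algorithm depends on
the specific base content.

Reads shorter than the insert plus anchoring context cannot contain a
complete junction reconstruction; with whole-amplicon fragments this
limits 150 bp reads to ITDs up to roughly 120 bp depending on position,
and is why the size-range tests switch to 300 bp reads for 108–206 bp
duplications — the same reason the bench assay does.

## Problem sizes in the test-suite and acceptance runs

Routine unit tests run at depths of 10³–4×10⁴ reads.  The analytical
headline checks use the protocol's own scales: ten wild-type samples at
10⁵ reads for specificity, and five-level ten-fold dilution series at
10⁶ reads per level (from 1% for the sensitivity floor, from 50% for
linearity — ten-fold factors are the natural choice for a serial
dilution when the bench factors are not specified).  The 30 bp reference
ITD used in these runs duplicates the 30 bases ending at amplicon offset
100, mid-amplicon, so both mates span its junctions.

## Numerical and degenerate-input choices

* Alignment ties break deterministically (match-state preferred, then
  insertion, then deletion; endpoint with the most read aligned); the
  oracle equivalence is on scores, where ties are irrelevant.
* An all-negative DP table returns the empty alignment (score 0, whole
  read clipped); the score floor of 20 then discards the read as
  unalignable.
* Candidate ordering (support descending, then anchor, then sequence)
  makes discovery output independent of read order.
* Homopolymeric or otherwise repetitive inserts can have no unique seed
  window; this is a explicit no-unique-seed signal, not a silent drop.
* VAF of an empty sample is an error, not 0: an empty read set is not a
  negative result.
* Empty candidate/measurement lists aggregate to VAF 0 (nothing traced).
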