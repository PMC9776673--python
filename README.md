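# seedtrace

Detection and longitudinal tracing of FLT3 internal tandem duplications
(ITDs) in single-amplicon deep sequencing, built for measurable-residual-
disease (MRD) monitoring in AML.

FLT3-ITDs are in-frame insertions in exons 14–15 that duplicate an
adjacent reference segment, usually with a short novel "spacer" between
the duplication copy and its origin.  Capillary fragment analysis, the
routine clinical assay, cannot see burdens below roughly 2% — far above
the residual disease levels that matter after therapy.  `seedtrace`
implements a sequencing-based alternative:

1. **Discover** — align amplicon reads (a 208 bp product over hg19
   chr13:28,608,108–28,608,315 by default), extract insertion and
   soft-clip junction evidence, and call ITDs by the identical-sequence
   support rule (> 3 identical junction reads out of > 10,000 total).
2. **Decompose** — split each insert into spacer + duplication and
   left-align it to a canonical record, so the same clone seen through
   different reads is one record.
3. **Seed** — designate a unique 12–20 bp *seed*: a window of the mutant
   molecule spanning the ITD junction, with ≥ 4 bases on each side of the
   junction, absent from the wild-type amplicon and its reverse
   complement.
4. **Track** — quantify MRD in any sample as the fraction of reads
   containing the seed exactly (either strand):
   `VAF = seed reads / total reads`, the programmatic equivalent of
   `samtools view sample.bam | grep <SEED> | wc -l`.  Multi-clone samples
   sum; repeat tests take the maximum; cut-off calls (2%, 0.1%, 0.01%,
   0.001%) are strict.
5. **LOD** — estimate the assay's limit of detection from a dilution
   series by probit regression: detection probability
   Φ(a + b·log₁₀ VAF), LOD at 95% probability with a delta-method CI.

A read simulator generates dilution series (FASTQ + truth SAM) with
known ITDs, depths to 10⁶ reads, and per-base substitution errors, so
the whole pipeline is testable without patient data.  The packaged
reference sequence is a synthetic stand-in with the real assay's
coordinates; any single-record FASTA of the right length drops in.

## Worked example

Simulate a diagnostic sample (30 bp ITD at 5% molecular VAF, 20,000
paired 150 bp reads), discover the clone and design its seed:

```
$ seedtrace simulate --itd 100:30:0.05 --total-reads 20000 --rng-seed 7 --out-dir sim
$ seedtrace discover sim/reads.fastq --out-dir diagnosis
$ cat diagnosis/itd_report.tsv
itd_id  genomic_anchor  itd_length  inserted_seq  duplication_seq  spacer_seq  in_frame  support  seed  seed_reads  total_reads  vaf_percent
itd_28608178_30  28608178  30  ACCTCGCTGCGCCACGACGTTCGACCTAGC  ACCTCGCTGCGCCACGACGTTCGACCTAGC    True  970  CCTAGCACCTCG  991  20000  4.955
```

One in-frame 30 bp duplication anchored at chr13:28,608,178, supported
by 970 identical junction reads; its 12 bp seed `CCTAGCACCTCG` is found
in 991 of 20,000 reads — a measured VAF of 4.96%, matching the simulated
5% within counting noise.  The seed manifest
(`diagnosis/seed_manifest.json`) is the portable tracer file.

Trace the same clone in a post-treatment sample simulated at 0.05% VAF
and 100,000 reads:

```
$ seedtrace simulate --itd 100:30:0.0005 --total-reads 100000 --rng-seed 8 --out-dir followup
$ seedtrace track followup/reads.fastq diagnosis/seed_manifest.json \
      --sample-id pt01 --timepoint post-1mo --out-dir mrd
$ cat mrd/mrd_summary.json
{
  "sample_id": "pt01",
  "timepoint": "post-1mo",
  "sample_vaf": 0.00045,
  "sample_vaf_percent": 0.045,
  "cutoff_calls_percent": {"2": false, "0.1": false, "0.01": true, "0.001": true},
  "finest_positive_percent": 0.001,
  ...
}
```

45 seed reads out of 100,000 give an MRD level of 0.045% — far below
fragment analysis's reach, positive at the 0.01% and 0.001% cut-offs and
negative at 0.1% and 2%.

The same operations are available as a library (`seedtrace.discover_itds`,
`seedtrace.track_sample`, `seedtrace.simulate_sample`,
`seedtrace.probit_lod`); see `docs/methods.md` for the model, parameter
choices and limitations.

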