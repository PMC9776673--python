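"""End-to-end workflows: discover ITDs and design seeds; track seeds.

``discover_itds`` chains alignment, junction extraction, exact-identity
clustering with the support/depth filter, spacer+duplication
decomposition, left-alignment, seed design and seed-count quantification.
``track_sample`` applies a previously designed seed manifest to a new
read set — the longitudinal MRD use case, where seeds designed at
diagnosis trace the clone through follow-up samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO

from .discovery import (
    MIN_SUPPORT,
    MIN_TOTAL_READS,
    AlignedRead,
    align_reads,
    cluster_and_filter,
    extract_junction_events,
)
from .mrd import MrdMeasurement, count_seed_reads
from .reference import AmpliconReference
from .seeds import (
    MAX_SEED_LEN,
    MIN_SEED_LEN,
    NoUniqueSeedError,
    SeedSequence,
    design_seed,
)
from .structure import (
    MIN_DUPLICATION,
    ItdRecord,
    NotAnItdError,
    canonical_itd,
)

__all__ = [
    "DiscoveredItd",
    "discover_itds",
    "track_sample",
    "read_fastq_sequences",
    "write_seed_manifest",
    "load_seed_manifest",
]


@dataclass
class DiscoveredItd:
    """One called ITD with its tracer seed and in-sample quantification."""

    record: ItdRecord
    seed: SeedSequence | None
    support: int
    seed_read_count: int
    total_reads: int

    @property
    def vaf(self) -> float:
        return self.seed_read_count / self.total_reads if self.total_reads else 0.0


def read_fastq_sequences(path: str) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fastq")]


def discover_itds(
    reads: Sequence[tuple[str, str]] | None,
    ref: AmpliconReference,
    alignments: Iterable[AlignedRead] | None = None,
    min_support: int = MIN_SUPPORT,
    min_total: int = MIN_TOTAL_READS,
    min_duplication: int = MIN_DUPLICATION,
    seed_min_len: int = MIN_SEED_LEN,
    seed_max_len: int = MAX_SEED_LEN,
) -> list[DiscoveredItd]:
    """Full discovery on one sample.

    Input is either raw reads (aligned internally) or pre-aligned records
    (e.g. from a SAM file, CIGARs trusted).  The total read count — the
    VAF denominator and the depth-filter denominator — is the number of
    input reads in FASTQ mode and of primary records in SAM mode.
    Candidate groups passing the support/depth filter are decomposed into
    spacer+duplication (failures are dropped as non-ITD insertions),
    left-aligned, unified per canonical record, and given a seed.  Sorted
    by support, descending.
    """
    if (reads is None) == (alignments is None):
        raise ValueError("provide exactly one of reads or alignments")
    seqs: list[str]
    if reads is not None:
        aligned = list(align_reads(reads, ref))
        total = len(reads)
        seqs = [s for _, s in reads]
    else:
        aligned = [a for a in alignments if not a.is_secondary]
        total = len(aligned)
        seqs = [a.sequence for a in aligned]

    candidates = extract_junction_events(aligned, ref)
    kept = cluster_and_filter(candidates, total, min_support=min_support, min_total=min_total)

    by_record: dict[ItdRecord, int] = {}
    for cand in kept:
        try:
            canonical = canonical_itd(
                ref, cand.anchor_pos, cand.junction_string, min_duplication=min_duplication
            )
        except (NotAnItdError, IndexError):
            continue
        by_record[canonical] = by_record.get(canonical, 0) + cand.support

    out: list[DiscoveredItd] = []
    for rec, support in by_record.items():
        try:
            seed = design_seed(rec, ref, seed_min_len, seed_max_len)
        except NoUniqueSeedError:
            seed = None
        n_seed = count_seed_reads(seqs, seed) if seed is not None else 0
        out.append(DiscoveredItd(rec, seed, support, n_seed, total))
    out.sort(key=lambda d: (-d.support, d.record.anchor_pos, d.record.inserted_seq))
    return out


def track_sample(
    reads: Sequence[tuple[str, str]] | Sequence[str],
    seeds: Sequence[SeedSequence],
    sample_id: str = "sample",
    timepoint: str | None = None,
) -> list[MrdMeasurement]:
    """Quantify every manifest seed in one read set."""
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    total = len(seqs)
    if total == 0:
        raise ValueError("no reads: VAF undefined for an empty sample")
    return [
        MrdMeasurement(
            sample_id=sample_id,
            itd_id=seed.itd_id,
            seed_read_count=count_seed_reads(seqs, seed),
            total_read_count=total,
            timepoint=timepoint,
        )
        for seed in seeds
    ]


def write_seed_manifest(path: str, discovered: Sequence[DiscoveredItd], ref: AmpliconReference) -> None:
    """Portable JSON manifest of designed seeds, the file carried across
    longitudinal samples."""
    entries = []
    for d in discovered:
        if d.seed is None:
            continue
        entries.append(
            {
                "itd_id": d.record.label,
                "seed": d.seed.bases,
                "length": len(d.seed.bases),
                "junction_offset": d.seed.junction_offset,
                "genomic_anchor": d.record.genomic_anchor,
                "itd_length": d.record.itd_length,
                "inserted_seq": d.record.inserted_seq,
                "duplication_seq": d.record.duplication_seq,
                "spacer_seq": d.record.spacer_seq,
                "in_frame": d.record.in_frame,
            }
        )
    meta = {
        "reference": ref.name,
        "genome_build": ref.genome_build,
        "region": f"{ref.chromosome}:{ref.genomic_start}-{ref.genomic_end}",
        "coordinate_note": "anchors are 1-based genomic, left-aligned placements",
        "vaf_note": "VAF denominator = all input reads (FASTQ) or primary records (SAM); no deduplication",
        "seeds": entries,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def load_seed_manifest(path: str) -> list[SeedSequence]:
    with open(path) as fh:
        meta = json.load(fh)
    return [
        SeedSequence(
            bases=e["seed"],
            itd_id=e["itd_id"],
            junction_offset=e["junction_offset"],
            occurrences_in_wildtype=0,
            occurrences_in_mutant=1,
        )
        for e in meta["seeds"]
    ]
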